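# Synthetic placeholder for a curated nitrogen-metabolism KO panel
# (urease, glutamine/glutamate synthesis, amino-acid production).
# Substitute the project's own curated KO identifiers (one per line).
K01427
K01428
K01429
K01430
K01915
K00265
K00266
K01745
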