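# Synthetic placeholder for a curated lignocellulose-digestion KO panel.
# Substitute the project's own curated KO identifiers (one per line).
K00001
K00845
K01179
K01181
K01188
K01225
K05349
K05350
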