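# Example end-to-end run on a simulated 13C-cellulose experiment.
#   sipflow run --config examples/config_cellulose.yaml
substrate: cellulose
life_stage: larva
rank: family
alpha: 0.05
tier_on: q
seed: 4
output_dir: sipflow_out
simulate:
  n_taxa: 30
  n_labeled: 3
  atom_excess: 0.75
  isotope: 13C
  n_fractions: 12
  reads_per_pool: 50000
  band_sigma: 0.006
  qpcr_cv: 0.10
  total_dna_ng: 750
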