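# Full-scale profile mirroring the reference study design:
# 54 replicates x daily host ages 5-60 d x three seed qualities,
# 100,000 resampling replicates.
seed: 0
design:
  n_replicates: 54
  age_start: 5
  age_stop: 60
  qualities: [90, 95, 100]
analysis:
  B: 100000
  tie_method: efron
  reference_quality: 100
  nominal_level: 0.05
  null_scheme: permutation
  nearest_age_fallback: true
  n_reference_per_cell: 40
io:
  out_dir: results/full
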