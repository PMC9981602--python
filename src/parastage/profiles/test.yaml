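# Reduced profile for tests and continuous integration: same structure,
# 10 replicates and 200 resampling replicates (Monte-Carlo error on a
# percentile p-value at B = 200 is about 0.03 near p = 0.05).
seed: 0
design:
  n_replicates: 10
  age_start: 5
  age_stop: 60
  qualities: [90, 95, 100]
analysis:
  B: 200
  tie_method: efron
  reference_quality: 100
  nominal_level: 0.05
  null_scheme: permutation
  nearest_age_fallback: true
  n_reference_per_cell: 30
  lambda_grid: [0.001, 0.1, 10.0, 1000.0, 100000.0, 10000000.0]
io:
  out_dir: results/test
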