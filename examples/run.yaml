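# Full-pipeline run on the default synthetic two-study trial.
seed: 7
out_dir: runs/demo

synth:
  missing_rate: 0.05
  outlier_rate: 0.01

model:
  n_trees: 300
  repeats: 10
  per_treatment: true
  tune: false

rfe:
  tolerance_pct: 5.0
  repeats: 10
  n_trees: 150

fit:
  k_sd: 1.0
  repeats: 10
  n_trees: 200
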