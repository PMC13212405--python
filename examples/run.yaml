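# Full benchmark configuration: 2-year synthetic station, 46 test gaps.
synthetic:
  n_hours: 17520
  seed: 0
  mechanism: MAR
  gap_rate: 2.0
plan:
  n_gaps: 46
  min_len: 25
  max_len: 72
gbt:
  n_trees: 600
  max_depth: 6
  learning_rate: 0.05
lstm:
  kind: lstm
  epochs: 8
rnn:
  kind: rnn
  epochs: 8
stats:
  alpha: 0.05
  bootstrap_B: 2000
max_train_windows: 8000
master_seed: 1
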