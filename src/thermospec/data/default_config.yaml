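# Default synthetic study configuration (mirrors pipeline.DEFAULT_CONFIG).
simulate:
  shape: [128, 128]
  n_channels: 204
  coverage: 0.35
  coupled_channels: [143]
  days: [1, 3, 6, 8, 12, 19, 25]
  stress_schedule: [0.0, 0.05, 0.2, 0.3, 0.6, 1.2, 2.0]
inputs: null
thr: [0.3]
ab:
  - [1.0, 1.0]
  - [0.5, 0.5]
channel_sets:
  - kind: extrema
    count: 5
  - kind: full
include_day: false
smooth_window: 5
best_channel: null
slp:
  max_epochs: 500
  patience: 20
  learning_rate: auto
seed: 0
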