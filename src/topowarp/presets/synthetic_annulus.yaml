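# Scaled-down single-structure study: annulus phantoms on a 64x64 grid.
model:
  l: 3
  f: 8
  l_bulk: 3
  l_ft: 2
  h: 8
  sigma: 2.0
  k: 3
  alpha: 10000.0
  beta: 10000.0
  T: 0.3
  c: 1
  use_bulk: true
  downsample_mode: maxpool
  lr: 0.001
  batch: 5
  epochs: 30
  seed: 0
data:
  task: myo
  H: 64
  W: 64
  n_samples: 400
  seed: 0
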