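# Digit-like single-structure phantoms in three topology classes,
# single-branch network (centred scenes need no bulk alignment).
model:
  l: 2
  f: 8
  l_bulk: 2
  l_ft: 1
  h: 8
  sigma: 2.0
  k: 3
  alpha: 150.0
  beta: 0.0
  T: 0.5
  c: 1
  use_bulk: false
  downsample_mode: maxpool
  lr: 0.001
  batch: 10
  epochs: 20
  seed: 0
data:
  task: digits
  H: 64
  W: 64
  n_samples: 300
  seed: 0
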