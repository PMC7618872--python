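# Cardiac myocardium configuration (144x208 crops, annulus prior of
# outer radius 35 and wall 7). Requires externally supplied MRI slices.
model:
  l: 4
  f: 12
  l_bulk: 4
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
  lr: 0.0001
  batch: 5
  epochs: 200
  seed: 0
data: {}
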