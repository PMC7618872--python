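# Digit segmentation configuration (28x28 inputs, single branch).
# Requires externally supplied digit images; no download is performed.
model:
  l: 2
  f: 12
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
  lr: 0.0001
  batch: 30
  epochs: 100
  seed: 0
data: {}
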