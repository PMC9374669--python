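# Canonical 15-layer detector architecture (240x240x3 -> 4x4x15).
input_shape:
- 240
- 240
- 3
activation: relu6
padding_mode: same_ceil
layers:
- index: 1
  kind: standard_conv
  stride: 2
  followed_by_bn: true
  bias: false
  conv_kernel:
  - 3
  - 3
  - 3
  - 32
- index: 2
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 32
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 32
  - 64
- index: 3
  kind: depthwise_separable
  stride: 2
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 64
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 64
  - 128
- index: 4
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 128
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 128
  - 128
- index: 5
  kind: depthwise_separable
  stride: 2
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 128
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 128
  - 256
- index: 6
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 256
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 256
  - 256
- index: 7
  kind: depthwise_separable
  stride: 2
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 256
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 256
  - 512
- index: 8
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 512
- index: 9
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 512
- index: 10
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 512
- index: 11
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 512
- index: 12
  kind: depthwise_separable
  stride: 1
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 512
- index: 13
  kind: depthwise_separable
  stride: 2
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 512
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 512
  - 1024
- index: 14
  kind: depthwise_separable
  stride: 2
  followed_by_bn: true
  bias: false
  depthwise_kernel:
  - 3
  - 3
  - 1024
  - 1
  pointwise_kernel:
  - 1
  - 1
  - 1024
  - 1024
- index: 15
  kind: standard_conv
  stride: 1
  followed_by_bn: false
  bias: true
  conv_kernel:
  - 1
  - 1
  - 1024
  - 15
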