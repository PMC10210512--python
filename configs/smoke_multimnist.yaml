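model:
  task: multimnist
  timesteps: 3
  glimpse_size: 18
  patch_size: 18
  conv_channels:
  - 32
  - 32
  conv_kernels:
  - 5
  - 3
  recurrent_size: 128
  n_primary: 40
  primary_dim: 8
  n_class: 10
  class_dim: 16
  routing_iterations: 3
  feedback: false
  variant: full
  response_idx:
  - 0
  - 1
loss:
  margin: 0.1
  lambda_absent: 0.5
  lambda_recon: 10.0
  masked: false
lr: 0.001
batch_size: 64
epochs: 6
seed: 0
n_train: 2000
n_val: 300
digit_source: fixtures
data_dir: null
out_dir: runs/smoke_multimnist
patience: null
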