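# Default training configuration. Any key may be omitted.
model:
  stage_channels: [32, 64, 128, 256, 256]
  kernel_mode: series        # or full3d
  crp_kernel: 5
  crp_blocks: 2
  dropout_rate: 0.2
  out_channels: 1
critic:
  block_channels: [64, 64, 32, 32]
  fc_units: 32
loss:
  alpha: 0.1                 # Dice weight; boundary weight is 1 - alpha
  reduction: mean
  adv_weight: 0.01           # lambda on the adversarial term
train:
  n_critic: 5
  clip_c: 0.01
  lr_generator: 5.0e-5
  lr_critic: 5.0e-5
  batch_size: 4
  max_steps: 100
  seed: 0
  alpha_schedule: false
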