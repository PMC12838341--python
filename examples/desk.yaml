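# Desk-scale preset: CPU-feasible end-to-end run (minutes per model).
seed: 1
out_dir: runs/desk
data:
  n_per_group: 200
  size: 64
  treated_ring_shift_sds: 2.0   # analytic ring-width effect size
preprocess:
  target_size: 64
  clahe: false   # synthetic blobs: CLAHE amplifies background noise
models:
  - kind: beta_vae
    latent_dim: 8
    beta: 6.0
    encoder_widths: [256, 128]
    decoder_widths: [128, 256]
  - kind: beta_tcvae
    latent_dim: 8
    alpha: 1.0
    beta: 6.0
    gamma: 1.0
    encoder_widths: [256, 128]
    decoder_widths: [128, 256]
  - kind: me_vae
    latent_dim: 8
    beta: 6.0
    encoder_widths: [256, 128]
    decoder_widths: [128, 256]
train:
  learning_rate: 5.0e-3
  weight_decay: 1.0e-5
  batch_size: 16
  epochs: 20
evaluate:
  top_k: 3
  bottom_k: 1
  traversal_steps: 7
  quantile: 0.95
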