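# cellvae

Unsupervised screening of two-group single-cell morphology with
variational autoencoders. Given grayscale single-cell images from a
"control" and a "treated" group, the pipeline

1. prepares the images (grayscale → CLAHE → unsharp-mask sharpening →
   resize → min–max normalization),
2. trains one of three generative models — **β-VAE**, **β-TCVAE** (with a
   minibatch mutual-information / total-correlation / dimension-wise-KL
   decomposition of the KL term) or **ME-VAE** (three parallel encoders
   over original, randomly rotated and polar-flipped views, averaged into
   one latent code),
3. ranks latent dimensions by Cohen's *d* between the groups (with 95%
   normal-approximation confidence intervals), draws kernel-density and
   violin summaries,
4. decodes latent traversals over [−3, 3] and localizes the structural
   change between the traversal extremes with absolute and SSIM-based
   difference maps plus a quantile-threshold mask.

Because no suitable public dataset accompanies this kind of study, the
package ships a synthetic generator (`cellvae.synthgen`): blob-like cells
with a bright membrane ring, darker interior and wavy boundary, whose
group-level factor shifts are configurable with analytically known effect
sizes — so the whole pipeline can be exercised and validated end to end
without any download.

The models are implemented on a small numpy reverse-mode autodiff engine
(`cellvae.autodiff`), so the package has no deep-learning-framework
dependency; everything runs on one CPU.

## CLI

All stages share one YAML config; each stage records its outputs (with
checksums) in `manifest.json` and later stages refuse to run on missing or
changed upstream outputs.

```bash
cellvae generate   --config run.yaml          # render synthetic PNGs
cellvae preprocess --config run.yaml          # preparation chain
cellvae train      --config run.yaml --model beta_vae
cellvae evaluate   --config run.yaml --model beta_vae
cellvae report     --config run.yaml          # Markdown report
cellvae run-all    --config run.yaml          # everything, all models
```

Minimal config (see `cellvae.config` for every knob; `desk_run_config()` /
`fullscale_run_config()` build the presets programmatically):

```yaml
seed: 1
out_dir: runs/desk
data: {n_per_group: 200, size: 64, treated_ring_shift_sds: 2.0}
preprocess: {target_size: 64, clahe: false}
models:
  - {kind: beta_vae, latent_dim: 8, beta: 6.0,
     encoder_widths: [256, 128], decoder_widths: [128, 256]}
train: {learning_rate: 5.0e-3, batch_size: 16, epochs: 20}
evaluate: {top_k: 3, bottom_k: 1, traversal_steps: 7, quantile: 0.95}
```

Exit codes: 0 success, 2 usage/config error, 3 data error.

Two presets are provided: the **desk** preset (64×64 frames, latent 8,
20 epochs, 200 images/group — minutes on one CPU) and the full-scale
preset (256×256, latent 32, β = 6, Adam lr 1e−4 / weight decay 1e−5 /
batch 16 / 150 epochs, 1000 images/group).

## Layout

```
src/cellvae/
  synthgen.py    two-group synthetic cell generator (ground truth retained)
  preprocess.py  grayscale / CLAHE / sharpen / resize / normalize chain
  autodiff.py    minimal reverse-mode autodiff over numpy
  models.py      β-VAE, β-TCVAE, ME-VAE and their losses
  train.py       Adam training loop, view augmentation, latent extraction
  evalstats.py   Cohen's d + CI + ranking, KDE, violin summaries
  traversal.py   latent traversal, absolute/SSIM difference maps
  config.py      YAML run configuration and presets
  cli.py         stage orchestration, manifest, report
tests/           unit + property tests; test_acceptance.py holds the
                 acceptance criteria (criterion 6 trains three models)
scripts/acceptance.py
```

## Conventions

* Effect size: d = (mean_treated − mean_control) / sqrt((s₁² + s₂²)/2)
  with n−1 variances; d > 0 means treated > control.
* Latent statistics always use posterior means (never sampled codes).
* MSE is summed over pixels and averaged over the batch; KL is summed over
  latent dimensions and averaged over the batch.
* SSIM: Gaussian window (σ 1.5, 11 taps), K1 = 0.01, K2 = 0.03, data
  range 1; dissimilarity maps are (1 − SSIM)/2.
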