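"""Generative models and losses: beta-VAE, beta-TCVAE and ME-VAE.

All three share a mirrored fully connected encoder/decoder pair built on
:mod:`cellvae.autodiff`. They differ in how the latent regularizer is
formed:

* beta-VAE: reconstruction + beta * KL(q(z|x) || N(0, I));
* beta-TCVAE: the KL is decomposed into mutual information, total
  correlation and dimension-wise KL via minibatch-weighted sampling, each
  with its own weight (alpha, beta, gamma);
* ME-VAE: three weight-independent encoders consume the original, rotated
  and polar-flipped views; their posteriors are averaged elementwise into
  one latent code which a single decoder maps back to the original view,
  trained with the beta-VAE objective.

Reconstruction error is the mean squared error summed over pixels and
averaged over the batch; KL terms are summed over latent dimensions and
averaged over the batch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "PosteriorParams",
    "LossBreakdown",
    "BetaVAE",
    "BetaTCVAE",
    "MEVAE",
    "build_model",
    "encode",
    "decode",
    "reparameterize",
    "kl_standard_normal",
    "beta_vae_loss",
    "tcvae_loss",
    "tc_decomposition",
    "aggregate_latents",
    "me_vae_forward",
    "save_checkpoint",
    "load_checkpoint",
]

MODEL_KINDS = ("beta_vae", "beta_tcvae", "me_vae")

LOGVAR_RANGE = (-8.0, 8.0)  # numeric safety clamp on encoder log-variances

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelConfig:
    kind: str = "beta_vae"
    latent_dim: int = 32
    beta: float = 6.0
    alpha: float = 1.0   # MI weight (beta-TCVAE only)
    gamma: float = 1.0   # dimension-wise KL weight (beta-TCVAE only)
    image_size: int = 64
    encoder_widths: tuple[int, ...] = (512, 256)
    decoder_widths: tuple[int, ...] = (256, 512)
    n_encoders: int = 3  # ME-VAE parallel encoders

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not self.encoder_widths or not self.decoder_widths:
            raise ValueError("encoder/decoder widths must be nonempty")
        if self.kind == "me_vae" and self.n_encoders != 3:
            raise ValueError("ME-VAE uses exactly 3 encoders")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "latent_dim": self.latent_dim,
            "beta": self.beta, "alpha": self.alpha, "gamma": self.gamma,
            "image_size": self.image_size,
            "encoder_widths": list(self.encoder_widths),
            "decoder_widths": list(self.decoder_widths),
            "n_encoders": self.n_encoders,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder_widths"] = tuple(d.get("encoder_widths", (512, 256)))
        d["decoder_widths"] = tuple(d.get("decoder_widths", (256, 512)))
        return cls(**d)


@dataclass(frozen=True)
class PosteriorParams:
    """Diagonal Gaussian posterior parameters q(z|x)."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=np.float64)
        logvar = np.asarray(self.logvar, dtype=np.float64)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "logvar", logvar)
        if mu.shape != logvar.shape:
            raise ValueError("mu and logvar must share a shape")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
            raise ValueError("posterior parameters must be finite")

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[-1]


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    reconstruction: float
    kl: float
    mi: float | None = None
    tc: float | None = None
    dimwise_kl: float | None = None

    def as_dict(self) -> dict:
        d = {"total": self.total, "reconstruction": self.reconstruction,
             "kl": self.kl}
        if self.mi is not None:
            d.update(mi=self.mi, tc=self.tc, dimwise_kl=self.dimwise_kl)
        return d


# ---------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)  # He init for ReLU stacks
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class _Encoder:
    """Flattened image -> hidden ReLU stack -> (mu, logvar) heads."""

    def __init__(self, n_pixels: int, widths: Sequence[int], latent_dim: int,
                 rng: np.random.Generator):
        dims = [n_pixels, *widths]
        self.hidden = [_Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.mu_head = _Linear(dims[-1], latent_dim, rng)
        self.logvar_head = _Linear(dims[-1], latent_dim, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for layer in self.hidden:
            h = layer(h).relu()
        mu = self.mu_head(h)
        logvar = self.logvar_head(h).clip(*LOGVAR_RANGE)
        return mu, logvar

    def parameters(self) -> list[Tensor]:
        params = [p for layer in self.hidden for p in layer.parameters()]
        return params + self.mu_head.parameters() + self.logvar_head.parameters()


class _Decoder:
    """Latent code -> hidden ReLU stack -> sigmoid image in [0, 1]."""

    def __init__(self, latent_dim: int, widths: Sequence[int], n_pixels: int,
                 rng: np.random.Generator):
        dims = [latent_dim, *widths, n_pixels]
        self.layers = [_Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, z: Tensor) -> Tensor:
        h = z
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        return self.layers[-1](h).sigmoid()

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


# ---------------------------------------------------------------------------
# loss pieces (tensor-level, reused by the numpy-facing public API)


def _gauss_kl_tensor(mu: Tensor, logvar: Tensor) -> Tensor:
    """Per-sample KL(q || N(0, I)), summed over latent dimensions."""
    return ((logvar.exp() + mu * mu - 1.0 - logvar) * 0.5).sum(axis=-1)


def _mse_tensor(x: Tensor, recon: Tensor) -> Tensor:
    """Squared error summed over pixels, averaged over the batch."""
    diff = x - recon
    return (diff * diff).sum(axis=-1).mean()


def _log_gauss_matrix(z: Tensor, mu: Tensor, logvar: Tensor) -> Tensor:
    """log q(z_i | x_j) for every pair: returns an (M, M) tensor."""
    m, latent = z.shape
    zi = z.reshape(m, 1, latent)
    muj = mu.reshape(1, m, latent)
    lvj = logvar.reshape(1, m, latent)
    d = zi - muj
    return (-0.5 * (Tensor(_LOG_2PI) + lvj + d * d / lvj.exp())).sum(axis=-1)


def _log_gauss_matrix_dimwise(z: Tensor, mu: Tensor, logvar: Tensor) -> Tensor:
    """log q(z_i,l | x_j) per dimension: returns an (M, M, L) tensor."""
    m, latent = z.shape
    zi = z.reshape(m, 1, latent)
    muj = mu.reshape(1, m, latent)
    lvj = logvar.reshape(1, m, latent)
    d = zi - muj
    return -0.5 * (Tensor(_LOG_2PI) + lvj + d * d / lvj.exp())


def _stratified_log_weights(m: int, dataset_size: int) -> np.ndarray:
    """Importance log-weights for the batch mixture estimate of q(z).

    The sampled code z_i came from q(z|x_i), so its own mixture component
    is certainly present in the batch; stratifying gives it weight 1/N and
    spreads the remaining (N-1)/N mass over the other M-1 components. With
    these weights the estimate is exact when every posterior equals the
    prior and matches 1/N * q(z|x_i) in the sharp-posterior regime.
    """
    logw = np.full((m, m), math.log(dataset_size - 1)
                   - math.log(dataset_size) - math.log(m - 1))
    np.fill_diagonal(logw, -math.log(dataset_size))
    return logw


def tc_decomposition(mu: Tensor | np.ndarray, logvar: Tensor | np.ndarray,
                     z: Tensor | np.ndarray,
                     dataset_size: int) -> tuple[Tensor, Tensor, Tensor]:
    """Minibatch estimates of (MI, TC, dimension-wise KL).

    Uses one sampled ``z`` per posterior; the aggregate posterior q(z) is
    approximated by the importance-weighted batch mixture (stratified
    weights built from the dataset size N and batch size M, see
    :func:`_stratified_log_weights`).
    """
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    logvar = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    z = z if isinstance(z, Tensor) else Tensor(z)
    m = z.shape[0]
    if m < 2:
        raise ValueError("the decomposition estimator needs a batch of >= 2")
    if dataset_size < m:
        raise ValueError("dataset_size must be >= batch size")
    logw = Tensor(_stratified_log_weights(m, dataset_size))

    # log q(z_i | x_i): diagonal of the pairwise matrix, computed directly
    d_own = z - mu
    log_qzx = (-0.5 * (Tensor(_LOG_2PI) + logvar + d_own * d_own / logvar.exp())
               ).sum(axis=-1)

    pair = _log_gauss_matrix(z, mu, logvar)                    # (M, M)
    pair_dim = _log_gauss_matrix_dimwise(z, mu, logvar)        # (M, M, L)
    log_qz = (pair + logw).logsumexp(axis=1)                   # (M,)
    log_qzl = (pair_dim + logw.reshape(m, m, 1)).logsumexp(axis=1)  # (M, L)
    log_prod_qzl = log_qzl.sum(axis=-1)                        # (M,)
    log_pz = (-0.5 * (Tensor(_LOG_2PI) + z * z)).sum(axis=-1)  # (M,)

    mi = (log_qzx - log_qz).mean()
    tc = (log_qz - log_prod_qzl).mean()
    dimwise = (log_prod_qzl - log_pz).mean()
    return mi, tc, dimwise


# ---------------------------------------------------------------------------
# models


class _VAEBase:
    kind: str

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.kind != self.kind:
            raise ValueError(f"config.kind {config.kind!r} != {self.kind!r}")
        self.config = config
        self.n_pixels = config.image_size ** 2
        rng = np.random.default_rng(seed)
        self._build(rng)

    # subclasses create encoders/decoder here
    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[1] * arr.shape[2] != self.n_pixels:
            raise ValueError(
                f"image shape {arr.shape[1:]} does not match configured size "
                f"{self.config.image_size}"
            )
        return arr.reshape(arr.shape[0], self.n_pixels)

    def encode_tensor(self, x: Tensor) -> tuple[Tensor, Tensor]:
        raise NotImplementedError

    def decode_tensor(self, z: Tensor) -> Tensor:
        raise NotImplementedError

    # numpy-facing API ----------------------------------------------------

    def encode(self, images: np.ndarray) -> PosteriorParams:
        x = Tensor(self._flatten(images))
        mu, logvar = self.encode_tensor(x)
        squeeze = np.asarray(images).ndim == 2
        mu_d, lv_d = mu.data, logvar.data
        if squeeze:
            mu_d, lv_d = mu_d[0], lv_d[0]
        return PosteriorParams(mu=mu_d, logvar=lv_d)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        squeeze = z.ndim == 1
        if squeeze:
            z = z[None]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent length {z.shape[1]} != configured {self.config.latent_dim}"
            )
        out = self.decode_tensor(Tensor(z)).data
        size = self.config.image_size
        out = out.reshape(-1, size, size)
        return out[0] if squeeze else out


class BetaVAE(_VAEBase):
    kind = "beta_vae"

    def _build(self, rng: np.random.Generator) -> None:
        c = self.config
        self.encoder = _Encoder(self.n_pixels, c.encoder_widths, c.latent_dim, rng)
        self.decoder = _Decoder(c.latent_dim, c.decoder_widths, self.n_pixels, rng)

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.decoder.parameters()

    def encode_tensor(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return self.encoder(x)

    def decode_tensor(self, z: Tensor) -> Tensor:
        return self.decoder(z)

    def loss(self, images: np.ndarray, rng: np.random.Generator,
             dataset_size: int | None = None) -> tuple[Tensor, LossBreakdown]:
        x = Tensor(self._flatten(images))
        mu, logvar = self.encode_tensor(x)
        eps = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        recon = self.decode_tensor(z)
        mse = _mse_tensor(x, recon)
        kl = _gauss_kl_tensor(mu, logvar).mean()
        total = mse + kl * self.config.beta
        return total, LossBreakdown(total=total.item(),
                                    reconstruction=mse.item(), kl=kl.item())


class BetaTCVAE(BetaVAE):
    kind = "beta_tcvae"

    def loss(self, images: np.ndarray, rng: np.random.Generator,
             dataset_size: int | None = None) -> tuple[Tensor, LossBreakdown]:
        if dataset_size is None:
            raise ValueError("beta-TCVAE loss requires the dataset size")
        c = self.config
        x = Tensor(self._flatten(images))
        mu, logvar = self.encode_tensor(x)
        eps = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        recon = self.decode_tensor(z)
        mse = _mse_tensor(x, recon)
        mi, tc, dimwise = tc_decomposition(mu, logvar, z, dataset_size)
        total = mse + mi * c.alpha + tc * c.beta + dimwise * c.gamma
        kl = _gauss_kl_tensor(mu, logvar).mean()
        return total, LossBreakdown(
            total=total.item(), reconstruction=mse.item(), kl=kl.item(),
            mi=mi.item(), tc=tc.item(), dimwise_kl=dimwise.item(),
        )


class MEVAE(_VAEBase):
    """Three parallel encoders over (original, rotated, polar) views."""

    kind = "me_vae"

    def _build(self, rng: np.random.Generator) -> None:
        c = self.config
        self.encoders = [
            _Encoder(self.n_pixels, c.encoder_widths, c.latent_dim, rng)
            for _ in range(c.n_encoders)
        ]
        self.decoder = _Decoder(c.latent_dim, c.decoder_widths, self.n_pixels, rng)

    def parameters(self) -> list[Tensor]:
        params = [p for enc in self.encoders for p in enc.parameters()]
        return params + self.decoder.parameters()

    def encode_views_tensor(self, views: Sequence[Tensor]) -> tuple[Tensor, Tensor]:
        if len(views) != len(self.encoders):
            raise ValueError(f"expected {len(self.encoders)} views")
        mus, logvars = zip(*(enc(v) for enc, v in zip(self.encoders, views)))
        n = float(len(mus))
        mu = sum(mus[1:], mus[0]) * (1.0 / n)
        logvar = sum(logvars[1:], logvars[0]) * (1.0 / n)
        return mu, logvar

    def encode_tensor(self, x: Tensor) -> tuple[Tensor, Tensor]:
        # single-view fallback: feed the same image to every encoder
        return self.encode_views_tensor([x] * len(self.encoders))

    def decode_tensor(self, z: Tensor) -> Tensor:
        return self.decoder(z)

    def encode_views(self, original: np.ndarray, rotated: np.ndarray,
                     polar_view: np.ndarray) -> PosteriorParams:
        views = [original, rotated, polar_view]
        shapes = {np.asarray(v).shape for v in views}
        if len(shapes) != 1:
            raise ValueError("the three views must share a shape")
        squeeze = np.asarray(original).ndim == 2
        tensors = [Tensor(self._flatten(v)) for v in views]
        mu, logvar = self.encode_views_tensor(tensors)
        mu_d, lv_d = mu.data, logvar.data
        if squeeze:
            mu_d, lv_d = mu_d[0], lv_d[0]
        return PosteriorParams(mu=mu_d, logvar=lv_d)

    def loss(self, views: Sequence[np.ndarray], rng: np.random.Generator,
             dataset_size: int | None = None) -> tuple[Tensor, LossBreakdown]:
        original, rotated, polar_view = views
        x = Tensor(self._flatten(original))
        tensors = [x, Tensor(self._flatten(rotated)),
                   Tensor(self._flatten(polar_view))]
        mu, logvar = self.encode_views_tensor(tensors)
        eps = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        recon = self.decode_tensor(z)
        # reconstruction target is the original, un-augmented view
        mse = _mse_tensor(x, recon)
        kl = _gauss_kl_tensor(mu, logvar).mean()
        total = mse + kl * self.config.beta
        return total, LossBreakdown(total=total.item(),
                                    reconstruction=mse.item(), kl=kl.item())


def build_model(config: ModelConfig, seed: int = 0) -> _VAEBase:
    cls = {"beta_vae": BetaVAE, "beta_tcvae": BetaTCVAE, "me_vae": MEVAE}[config.kind]
    return cls(config, seed=seed)


# ---------------------------------------------------------------------------
# public functional API


def encode(model: _VAEBase, images: np.ndarray) -> PosteriorParams:
    return model.encode(images)


def decode(model: _VAEBase, z: np.ndarray) -> np.ndarray:
    return model.decode(z)


def reparameterize(p: PosteriorParams, rng: np.random.Generator) -> np.ndarray:
    """Sample z = mu + sigma * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(p.mu.shape)
    return p.mu + np.exp(p.logvar / 2.0) * eps


def kl_standard_normal(p: PosteriorParams) -> np.ndarray:
    """Closed-form KL(q || N(0, I)) per sample, summed over dimensions."""
    kl = 0.5 * (np.exp(p.logvar) + p.mu ** 2 - 1.0 - p.logvar)
    return kl.sum(axis=-1)


def beta_vae_loss(x: np.ndarray, reconstruction: np.ndarray,
                  p: PosteriorParams, beta: float) -> LossBreakdown:
    """MSE (pixel-sum, batch-mean) + beta * KL (dimension-sum, batch-mean)."""
    x = np.asarray(x, dtype=np.float64)
    recon = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != recon.shape:
        raise ValueError("input and reconstruction shapes differ")
    if x.ndim == 2:
        x, recon = x[None], recon[None]
    n = x.shape[0]
    mse = float(((x - recon) ** 2).reshape(n, -1).sum(axis=1).mean())
    kl = float(np.mean(kl_standard_normal(p)))
    return LossBreakdown(total=mse + beta * kl, reconstruction=mse, kl=kl)


def tcvae_loss(x: np.ndarray, reconstruction: np.ndarray, p: PosteriorParams,
               z: np.ndarray, alpha: float, beta: float, gamma: float,
               dataset_size: int) -> LossBreakdown:
    """MSE plus the weighted (MI, TC, dimension-wise KL) decomposition."""
    x = np.asarray(x, dtype=np.float64)
    recon = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != recon.shape:
        raise ValueError("input and reconstruction shapes differ")
    n = x.shape[0]
    if n < 2:
        raise ValueError("the decomposition estimator needs a batch of >= 2")
    mse = float(((x - recon) ** 2).reshape(n, -1).sum(axis=1).mean())
    mi, tc, dimwise = tc_decomposition(p.mu, p.logvar, np.asarray(z),
                                       dataset_size)
    mi_v, tc_v, dw_v = mi.item(), tc.item(), dimwise.item()
    kl = float(np.mean(kl_standard_normal(p)))
    return LossBreakdown(
        total=mse + alpha * mi_v + beta * tc_v + gamma * dw_v,
        reconstruction=mse, kl=kl, mi=mi_v, tc=tc_v, dimwise_kl=dw_v,
    )


def aggregate_latents(z1: np.ndarray, z2: np.ndarray,
                      z3: np.ndarray) -> np.ndarray:
    """Elementwise mean of the three encoder outputs."""
    z1, z2, z3 = (np.asarray(z, dtype=np.float64) for z in (z1, z2, z3))
    if not z1.shape == z2.shape == z3.shape:
        raise ValueError("latent vectors must share a shape")
    return (z1 + z2 + z3) / 3.0


def me_vae_forward(model: MEVAE, original: np.ndarray, rotated: np.ndarray,
                   polar_view: np.ndarray,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, PosteriorParams, LossBreakdown]:
    """One ME-VAE pass: encode three views, aggregate, decode, score.

    With no ``rng``, the decoder consumes the posterior mean (deterministic).
    """
    if not isinstance(model, MEVAE):
        raise TypeError("me_vae_forward requires an MEVAE model")
    p = model.encode_views(original, rotated, polar_view)
    z = reparameterize(p, rng) if rng is not None else p.mu
    recon = model.decode(z)
    loss = beta_vae_loss(original, recon, p, model.config.beta)
    return recon, p, loss


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: _VAEBase, path: str | Path, seed: int = 0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(model.config.to_dict()),
             seed=seed, **arrays)


def load_checkpoint(path: str | Path) -> _VAEBase:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["config"])))
        model = build_model(config, seed=int(data["seed"]))
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].copy()
    return model
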