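"""Training protocol and latent extraction.

Adam with weight decay, fixed batch size and epoch count; ME-VAE batches
additionally carry a randomly rotated view and a polar-flip view of every
image. Latents for downstream statistics are posterior means (never
sampled), so extraction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as _nd_rotate
from skimage.transform import warp_polar

from .autodiff import Tensor
from .models import (LossBreakdown, ModelConfig, build_model, save_checkpoint)
from .preprocess import CellImage
from .synthgen import SyntheticDataset

__all__ = [
    "TrainConfig",
    "LatentMatrix",
    "make_views",
    "polar_resample",
    "train_model",
    "extract_latents",
    "as_image_stack",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 16
    epochs: int = 150
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    def to_dict(self) -> dict:
        return {"learning_rate": self.learning_rate,
                "weight_decay": self.weight_decay,
                "batch_size": self.batch_size, "epochs": self.epochs,
                "seed": self.seed, "optimizer": self.optimizer}


@dataclass
class LatentMatrix:
    """Posterior means (n x L) with aligned group labels and source ids."""

    values: np.ndarray
    labels: list[str]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be an n x L matrix")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must align with rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")
        if not self.source_ids:
            self.source_ids = [str(i) for i in range(self.values.shape[0])]

    @property
    def latent_dim(self) -> int:
        return self.values.shape[1]

    def group(self, label: str) -> np.ndarray:
        mask = np.array([lab == label for lab in self.labels])
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"z_{j}": self.values[:, j] for j in range(self.latent_dim)}
        frame = pd.DataFrame(cols)
        frame["label"] = self.labels
        frame["source_id"] = self.source_ids
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LatentMatrix":
        frame = pd.read_csv(path)
        z_cols = [c for c in frame.columns if c.startswith("z_")]
        return cls(values=frame[z_cols].to_numpy(),
                   labels=list(frame["label"].astype(str)),
                   source_ids=list(frame["source_id"].astype(str)))


# ---------------------------------------------------------------------------
# views


def _rotate(image: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return image.copy()
    out = _nd_rotate(image, angle_deg, reshape=False, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def polar_flip(image: np.ndarray) -> np.ndarray:
    """Horizontal then vertical reflection — exactly a 180-degree rotation."""
    return image[::-1, ::-1].copy()


def polar_resample(image: np.ndarray) -> np.ndarray:
    """Alternative polar view: resample onto (angle, radius) coordinates."""
    out = warp_polar(image, output_shape=image.shape)
    return np.clip(out, 0.0, 1.0)


def make_views(image: np.ndarray | CellImage, rng: np.random.Generator,
               polar_mode: str = "flip") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the (original, rotated, polar) triplet for one image.

    The rotation angle is uniform in [-180, 180] degrees with bilinear
    interpolation and reflective padding; the polar view is the composed
    horizontal+vertical flip by default, or a polar-coordinate resampling
    when ``polar_mode='resample'``.
    """
    arr = image.pixels if isinstance(image, CellImage) else np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("make_views expects a square single-channel image")
    angle = float(rng.uniform(-180.0, 180.0))
    rotated = _rotate(arr, angle)
    if polar_mode == "flip":
        polar_view = polar_flip(arr)
    elif polar_mode == "resample":
        polar_view = polar_resample(arr)
    else:
        raise ValueError("polar_mode must be 'flip' or 'resample'")
    return arr.copy(), rotated, polar_view


# ---------------------------------------------------------------------------
# dataset adapters


def as_image_stack(dataset) -> tuple[np.ndarray, list[str], list[str]]:
    """Coerce supported dataset flavors to (n, H, W) stack + labels + ids."""
    if isinstance(dataset, SyntheticDataset):
        stack = np.stack(dataset.images)
        labels = list(dataset.labels)
        ids = [str(i) for i in range(len(labels))]
    elif isinstance(dataset, LatentMatrix):
        raise TypeError("expected images, got a LatentMatrix")
    elif len(dataset) and isinstance(dataset[0], CellImage):
        stack = np.stack([im.pixels for im in dataset])
        labels = [im.group for im in dataset]
        ids = [im.source_id or str(i) for i, im in enumerate(dataset)]
    else:
        stack = np.asarray(dataset, dtype=np.float64)
        if stack.ndim != 3:
            raise ValueError("expected an (n, H, W) stack of images")
        labels = [""] * stack.shape[0]
        ids = [str(i) for i in range(stack.shape[0])]
    return stack, labels, ids


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# training


def train_model(dataset, model_config: ModelConfig, train_config: TrainConfig,
                checkpoint_path: str | Path | None = None,
                progress: bool = False):
    """Train one model on a stack of preprocessed images.

    Returns ``(model, history)`` where ``history`` holds one averaged
    :class:`LossBreakdown` per epoch. Fully seeded: weight init, shuffling,
    reparameterization noise and view augmentation all derive from
    ``train_config.seed``.
    """
    stack, _, _ = as_image_stack(dataset)
    n = stack.shape[0]
    if n == 0:
        raise ValueError("dataset is empty")
    if stack.shape[1] != model_config.image_size:
        raise ValueError(
            f"dataset images are {stack.shape[1]}x{stack.shape[2]} but the "
            f"model expects {model_config.image_size}"
        )
    rng = np.random.default_rng(train_config.seed)
    model = build_model(model_config, seed=train_config.seed)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate,
                     weight_decay=train_config.weight_decay)
    is_mevae = model_config.kind == "me_vae"

    history: list[LossBreakdown] = []
    epochs = range(train_config.epochs)
    if progress:
        from tqdm import tqdm
        epochs = tqdm(epochs, desc=f"train {model_config.kind}")
    for _ in epochs:
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch = stack[idx]
            if is_mevae:
                views = [make_views(img, rng) for img in batch]
                triplet = [np.stack([v[k] for v in views]) for k in range(3)]
                loss, breakdown = model.loss(triplet, rng, dataset_size=n)
            else:
                loss, breakdown = model.loss(batch, rng, dataset_size=n)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            for key, val in breakdown.as_dict().items():
                sums[key] = sums.get(key, 0.0) + val
            n_batches += 1
        means = {k: v / n_batches for k, v in sums.items()}
        history.append(LossBreakdown(**means))
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, seed=train_config.seed)
    return model, history


def history_frame(history: Sequence[LossBreakdown]) -> pd.DataFrame:
    frame = pd.DataFrame([h.as_dict() for h in history])
    frame.insert(0, "epoch", np.arange(len(history)))
    return frame


def extract_latents(model, dataset, batch_size: int = 256) -> LatentMatrix:
    """Posterior means per image; deterministic (no sampling).

    For the ME-VAE the three views are fixed: rotation angle 0 (so the
    rotated view is the original) and the exact polar flip.
    """
    stack, labels, ids = as_image_stack(dataset)
    rows = []
    for start in range(0, stack.shape[0], batch_size):
        batch = stack[start:start + batch_size]
        if model.config.kind == "me_vae":
            polar = np.stack([polar_flip(img) for img in batch])
            p = model.encode_views(batch, batch.copy(), polar)
        else:
            p = model.encode(batch)
        rows.append(p.mu)
    return LatentMatrix(values=np.vstack(rows), labels=labels, source_ids=ids)
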