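"""Latent traversal decoding and difference-map localization.

A traversal sweeps one latent coordinate linearly over [-3, 3] around a
baseline code and decodes each point. Difference maps compare the decoded
endpoints (-3 vs +3) pixelwise, both as absolute differences and as a
windowed structural-similarity (SSIM) dissimilarity field, then threshold
the dissimilarity at a quantile to mark the most-changed regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .evalstats import EffectSizeTable

__all__ = [
    "TraversalResult",
    "DifferenceMap",
    "traverse",
    "abs_difference_map",
    "ssim_map",
    "mean_ssim",
    "threshold_map",
    "difference_report",
]

# canonical SSIM constants (data range 1)
_K1, _K2 = 0.01, 0.03
_C1, _C2 = (_K1 ** 2), (_K2 ** 2)
_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # gives an 11-tap kernel at sigma 1.5


@dataclass(frozen=True)
class TraversalResult:
    dimension: int
    values: np.ndarray
    images: np.ndarray          # (n_steps, H, W)
    baseline: np.ndarray
    context: str = "zero"       # which baseline was used

    def __post_init__(self):
        if self.images.shape[0] != self.values.shape[0]:
            raise ValueError("one decoded image per traversal value required")


@dataclass(frozen=True)
class DifferenceMap:
    dimension: int
    absolute: np.ndarray
    ssim_dissimilarity: np.ndarray
    mask: np.ndarray
    rank: int | None = None

    @property
    def mean_abs(self) -> float:
        return float(self.absolute.mean())

    @property
    def mean_dissimilarity(self) -> float:
        return float(self.ssim_dissimilarity.mean())

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


def traverse(model, dim: int, n_steps: int = 7,
             baseline: np.ndarray | None = None,
             context: str = "zero",
             low: float = -3.0, high: float = 3.0) -> TraversalResult:
    """Decode a linear sweep of one latent coordinate.

    ``baseline`` defaults to the zero vector; pass a group-mean latent to
    reproduce per-group traversal panels.
    """
    latent_dim = model.config.latent_dim
    if not 0 <= dim < latent_dim:
        raise ValueError(f"dim {dim} out of range for latent_dim {latent_dim}")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if baseline is None:
        baseline = np.zeros(latent_dim)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != (latent_dim,):
        raise ValueError("baseline must be a latent_dim vector")
    values = np.linspace(low, high, n_steps)
    codes = np.tile(baseline, (n_steps, 1))
    codes[:, dim] = values
    images = model.decode(codes)
    return TraversalResult(dimension=dim, values=values, images=images,
                           baseline=baseline.copy(), context=context)


def abs_difference_map(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference."""
    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    return np.abs(img_a - img_b)


def _ssim_field(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Per-pixel SSIM with a Gaussian window (sigma 1.5, 11 taps)."""
    filt = lambda im: gaussian_filter(im, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    mu_a, mu_b = filt(img_a), filt(img_b)
    var_a = filt(img_a * img_a) - mu_a * mu_a
    var_b = filt(img_b * img_b) - mu_b * mu_b
    cov = filt(img_a * img_b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + _C1) * (2 * cov + _C2)
    den = (mu_a * mu_a + mu_b * mu_b + _C1) * (var_a + var_b + _C2)
    return num / den


def ssim_map(img_a: np.ndarray, img_b: np.ndarray,
             return_dissimilarity: bool = False) -> np.ndarray:
    """Windowed per-pixel structural similarity in [-1, 1].

    With ``return_dissimilarity`` the field is mapped to (1 - SSIM)/2,
    which lies in [0, 1] (0 = identical structure).
    """
    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    field = _ssim_field(img_a, img_b)
    if return_dissimilarity:
        return (1.0 - field) / 2.0
    return field


def mean_ssim(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Scalar SSIM: the per-pixel field averaged over the interior.

    The border of half the window width is excluded, matching the
    reference implementation's crop.
    """
    field = ssim_map(img_a, img_b)
    # half of the 11-tap window: int(truncate * sigma + 0.5) = 5
    pad = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)
    return float(field[pad:-pad, pad:-pad].mean())


def threshold_map(dissimilarity: np.ndarray, quantile: float = 0.95) -> np.ndarray:
    """Boolean mask of pixels at or above the given dissimilarity quantile.

    A constant field ties everywhere and yields an all-True mask.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    dissimilarity = np.asarray(dissimilarity, dtype=np.float64)
    cut = np.quantile(dissimilarity, quantile)
    return dissimilarity >= cut


def difference_report(model, table: EffectSizeTable, top_k: int = 2,
                      bottom_k: int = 1, quantile: float = 0.95,
                      baseline: np.ndarray | None = None) -> list[DifferenceMap]:
    """Difference maps at the traversal extremes for ranked dimensions.

    Covers the ``top_k`` highest-|d| and ``bottom_k`` lowest-|d| dimensions;
    each map compares the decoded images at latent values -3 and +3.
    """
    if top_k + bottom_k > table.latent_dim:
        raise ValueError("top_k + bottom_k exceeds the latent dimensionality")
    dims = list(table.top(top_k)) + list(table.bottom(bottom_k))
    maps: list[DifferenceMap] = []
    for dim in dims:
        sweep = traverse(model, int(dim), n_steps=2, baseline=baseline)
        lo_img, hi_img = sweep.images[0], sweep.images[-1]
        dissim = ssim_map(lo_img, hi_img, return_dissimilarity=True)
        maps.append(DifferenceMap(
            dimension=int(dim),
            absolute=abs_difference_map(lo_img, hi_img),
            ssim_dissimilarity=dissim,
            mask=threshold_map(dissim, quantile),
            rank=int(table.rank[dim]),
        ))
    return maps
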