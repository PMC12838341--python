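"""Latent-space group comparison: effect sizes, densities, violins.

The effect size per latent dimension is the standardized mean difference

    d_i = (mean_treated_i - mean_control_i) / sqrt((s1_i^2 + s2_i^2) / 2)

with n-1 sample variances; positive d means the treated group sits higher.
Confidence intervals use the large-sample normal approximation
d +/- z * sqrt((n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .train import LatentMatrix

__all__ = [
    "EffectSizeTable",
    "DensityCurve",
    "ViolinSummary",
    "cohens_d",
    "cohens_d_ci",
    "effect_size_table",
    "kde",
    "violin_summary",
    "overlap_coefficient",
]


@dataclass(frozen=True)
class EffectSizeTable:
    """Per-dimension effect sizes, CIs, ranks and group summary stats."""

    d: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rank: np.ndarray          # 1 = largest |d|
    mean_control: np.ndarray
    mean_treated: np.ndarray
    sd_control: np.ndarray
    sd_treated: np.ndarray
    pooled_sd: np.ndarray
    n_control: int
    n_treated: int
    control_label: str = "control"
    treated_label: str = "treated"

    @property
    def latent_dim(self) -> int:
        return self.d.shape[0]

    def dims_by_rank(self) -> np.ndarray:
        """Dimension indices ordered rank 1, 2, ... (descending |d|)."""
        return np.argsort(self.rank)

    def top(self, k: int) -> np.ndarray:
        if k > self.latent_dim:
            raise ValueError(f"k={k} exceeds the {self.latent_dim} dimensions")
        return self.dims_by_rank()[:k]

    def bottom(self, k: int) -> np.ndarray:
        if k > self.latent_dim:
            raise ValueError(f"k={k} exceeds the {self.latent_dim} dimensions")
        return self.dims_by_rank()[::-1][:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dimension": np.arange(self.latent_dim),
            "d": self.d, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "rank": self.rank,
            "mean_control": self.mean_control, "mean_treated": self.mean_treated,
            "sd_control": self.sd_control, "sd_treated": self.sd_treated,
            "pooled_sd": self.pooled_sd,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    label: str = ""

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ViolinSummary:
    median: float
    q1: float
    q3: float
    low: float
    high: float

    def __post_init__(self):
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must satisfy q1 <= median <= q3")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference mean(b) - mean(a) over the pooled sd.

    ``a`` is the control sample and ``b`` the treated sample, so d > 0
    means treated exceeds control. The pooled sd is the unweighted
    root-mean-square of the two n-1 sample sds (equal-n convention).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt((va + vb) / 2.0)
    if pooled == 0.0:
        raise ValueError("effect size undefined: both samples are degenerate")
    return float((b.mean() - a.mean()) / pooled)


def cohens_d_ci(d: float, n1: int, n2: int,
                level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval for an effect size."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    z = sps.norm.ppf((1.0 + level) / 2.0)
    return d - z * se, d + z * se


def effect_size_table(latents: LatentMatrix, control_label: str = "control",
                      treated_label: str = "treated",
                      level: float = 0.95) -> EffectSizeTable:
    """Effect size, CI and |d| rank for every latent dimension."""
    a = latents.group(control_label)
    b = latents.group(treated_label)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"both groups ({control_label!r}, {treated_label!r}) need >= 2 rows"
        )
    latent_dim = latents.latent_dim
    d = np.empty(latent_dim)
    lo = np.empty(latent_dim)
    hi = np.empty(latent_dim)
    for j in range(latent_dim):
        d[j] = cohens_d(a[:, j], b[:, j])
        lo[j], hi[j] = cohens_d_ci(d[j], a.shape[0], b.shape[0], level)
    # rank 1 = largest |d|; ties broken by the lower dimension index
    order = np.lexsort((np.arange(latent_dim), -np.abs(d)))
    rank = np.empty(latent_dim, dtype=int)
    rank[order] = np.arange(1, latent_dim + 1)
    return EffectSizeTable(
        d=d, ci_low=lo, ci_high=hi, rank=rank,
        mean_control=a.mean(axis=0), mean_treated=b.mean(axis=0),
        sd_control=a.std(axis=0, ddof=1), sd_treated=b.std(axis=0, ddof=1),
        pooled_sd=np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2.0),
        n_control=a.shape[0], n_treated=b.shape[0],
        control_label=control_label, treated_label=treated_label,
    )


def kde(values: np.ndarray, bandwidth: float | str = "scott",
        grid_size: int = 512, label: str = "") -> DensityCurve:
    """Gaussian-kernel density on a grid spanning the data +/- 3 bandwidths."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("kde needs at least 2 observations")
    if values.std(ddof=1) == 0:
        raise ValueError("kde undefined for a zero-variance sample")
    if bandwidth == "scott":
        bw = float(values.std(ddof=1) * values.size ** (-1.0 / 5.0))
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be > 0")
    grid = np.linspace(values.min() - 3.0 * bw, values.max() + 3.0 * bw,
                       grid_size)
    # direct Gaussian mixture evaluation (values.size x grid_size)
    z = (grid[None, :] - values[:, None]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=0) / (
        values.size * bw * math.sqrt(2.0 * math.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=bw, label=label)


def violin_summary(values: np.ndarray) -> ViolinSummary:
    """Median and linear-interpolation quartiles plus the support range."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 4:
        raise ValueError("violin_summary needs at least 4 observations")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return ViolinSummary(median=float(med), q1=float(q1), q3=float(q3),
                         low=float(values.min()), high=float(values.max()))


def overlap_coefficient(curve_a: DensityCurve, curve_b: DensityCurve) -> float:
    """Integral of min(f, g) over a shared grid; 1 = identical densities."""
    lo = min(curve_a.grid[0], curve_b.grid[0])
    hi = max(curve_a.grid[-1], curve_b.grid[-1])
    grid = np.linspace(lo, hi, 2048)
    fa = np.interp(grid, curve_a.grid, curve_a.density, left=0.0, right=0.0)
    fb = np.interp(grid, curve_b.grid, curve_b.density, left=0.0, right=0.0)
    return float(np.trapezoid(np.minimum(fa, fb), grid))
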