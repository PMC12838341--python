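"""Figure helpers for the CLI evaluation and report stages."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .evalstats import DensityCurve, EffectSizeTable
from .traversal import DifferenceMap, TraversalResult


def forest_plot(table: EffectSizeTable, path: Path) -> None:
    order = table.dims_by_rank()
    y = np.arange(table.latent_dim)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * table.latent_dim)))
    ax.errorbar(table.d[order], y,
                xerr=[table.d[order] - table.ci_low[order],
                      table.ci_high[order] - table.d[order]],
                fmt="o", ms=3, capsize=2, lw=1)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([f"z_{i}" for i in order], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("Cohen's d (treated - control), 95% CI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def kde_plot(curves: list[DensityCurve], path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for curve in curves:
        ax.plot(curve.grid, curve.density, label=curve.label)
        ax.fill_between(curve.grid, curve.density, alpha=0.25)
    ax.set_xlabel("latent value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def violin_plot(samples: dict[str, np.ndarray], path: Path,
                title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 3.2))
    labels = list(samples)
    parts = ax.violinplot([samples[k] for k in labels], showmedians=True)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    ax.set_xticks(np.arange(1, len(labels) + 1))
    ax.set_xticklabels(labels, fontsize=8)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def traversal_strip(result: TraversalResult, path: Path) -> None:
    n = result.images.shape[0]
    fig, axes = plt.subplots(1, n, figsize=(1.2 * n, 1.5))
    for ax, value, img in zip(np.atleast_1d(axes), result.values,
                              result.images):
        ax.imshow(img, cmap="gray", vmin=0, vmax=1)
        ax.set_title(f"{value:+.1f}", fontsize=7)
        ax.axis("off")
    fig.suptitle(f"z_{result.dimension} ({result.context} baseline)",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def difference_panel(dmap: DifferenceMap, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(7, 2.4))
    for ax, (title, img, cmap) in zip(axes, [
        ("absolute |Δ|", dmap.absolute, "magma"),
        ("SSIM dissimilarity", dmap.ssim_dissimilarity, "magma"),
        ("thresholded mask", dmap.mask.astype(float), "gray"),
    ]):
        im = ax.imshow(img, cmap=cmap)
        ax.set_title(title, fontsize=8)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.suptitle(f"z_{dmap.dimension} (rank {dmap.rank})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
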