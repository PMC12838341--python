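"""Image preparation: grayscale -> CLAHE -> sharpen -> resize -> min-max.

The chain runs in that fixed order and records each applied stage in the
output's provenance, so downstream code (and tests) can assert the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve
from skimage import exposure
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreprocessConfig",
    "CellImage",
    "to_grayscale",
    "apply_clahe",
    "sharpen",
    "resize",
    "minmax_normalize",
    "preprocess_pipeline",
    "load_image",
]

# luminance weights (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])

# cross-shaped 3x3 blur: at strength 1 the unsharp mask reduces to the
# classic [[0,-1,0],[-1,5,-1],[0,-1,0]] sharpening kernel
_BLUR_KERNEL = np.array([[0.0, 0.25, 0.0],
                         [0.25, 0.0, 0.25],
                         [0.0, 0.25, 0.0]])


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preparation chain; defaults are conventional values
    (the source protocol names the stages but not their parameters)."""

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    sharpen_strength: float = 1.0
    target_size: int = 64
    grayscale: bool = True
    clahe: bool = True
    do_sharpen: bool = True
    do_resize: bool = True
    normalize: bool = True

    def __post_init__(self):
        if self.target_size < 16:
            raise ValueError("target_size must be >= 16")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid entries must be >= 1")
        if self.sharpen_strength < 0:
            raise ValueError("sharpen_strength must be >= 0")


@dataclass
class CellImage:
    """A preprocessed grayscale image with label and provenance."""

    pixels: np.ndarray
    group: str = ""
    source_id: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 1- or 3-channel image to a single luminance channel."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise ValueError(f"expected 1 or 3 channels, got shape {image.shape}")


def apply_clahe(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] grid.

    ``clahe_clip_limit`` follows the OpenCV convention (multiples of the
    uniform histogram height); it is converted to skimage's fractional
    clip limit internally. Constant images pass through unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("apply_clahe expects a single-channel image")
    if np.ptp(image) < 1e-12:  # degenerate histogram: nothing to equalize
        return image.copy()
    rows, cols = config.clahe_tile_grid
    kernel = (max(image.shape[0] // rows, 1), max(image.shape[1] // cols, 1))
    clip = min(config.clahe_clip_limit / 256.0, 1.0)
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=clip
    )
    return np.clip(out, 0.0, 1.0)


def sharpen(image: np.ndarray, strength: float) -> np.ndarray:
    """Unsharp mask: ``clip(x + strength * (x - blur(x)), 0, 1)``."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("sharpen expects a single-channel image")
    if strength == 0:
        return image.copy()
    blurred = convolve(image, _BLUR_KERNEL, mode="nearest")
    return np.clip(image + strength * (image - blurred), 0.0, 1.0)


def resize(image: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear anti-aliased resize to a square ``target_size`` grid."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape == (target_size, target_size):
        return image.copy()
    return _sk_resize(image, (target_size, target_size), order=1,
                      anti_aliasing=True, preserve_range=True)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Map to [0, 1] via (v - min)/(max - min); constant images map to zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("minmax_normalize requires finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def preprocess_pipeline(image: np.ndarray, config: PreprocessConfig,
                        group: str = "", source_id: str = "") -> CellImage:
    """Run the full stage chain in its fixed order and record provenance."""
    provenance: list[str] = []
    out = np.asarray(image, dtype=np.float64)
    if config.grayscale:
        out = to_grayscale(out)
        provenance.append("grayscale")
    elif out.ndim != 2:
        raise ValueError("non-grayscale pipeline requires 2-D input")
    if config.clahe:
        out = apply_clahe(out, config)
        provenance.append("clahe")
    if config.do_sharpen:
        out = sharpen(out, config.sharpen_strength)
        provenance.append("sharpen")
    if config.do_resize:
        out = resize(out, config.target_size)
        provenance.append("resize")
    if config.normalize:
        out = minmax_normalize(out)
        provenance.append("normalize")
    return CellImage(pixels=out, group=group, source_id=source_id,
                     provenance=provenance)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF into a float array scaled to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    if arr.size and arr.max() > 1.0:
        arr = arr / 255.0
    return arr
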