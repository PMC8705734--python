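"""Fundus preprocessing: green channel, CLAHE, median filter, min-max
normalization, adaptive gamma, and multi-scale morphological enhancement.

Stages operate on 2-D float arrays. The pipeline output is a "unit image":
a float64 grid with every value in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from skimage.exposure import equalize_adapthist
from skimage.morphology import black_tophat, disk, white_tophat

from .io import FundusImage

__all__ = [
    "PreprocessConfig",
    "extract_green",
    "clahe",
    "median_denoise",
    "minmax_normalize",
    "adaptive_gamma",
    "multiscale_enhance",
    "preprocess_pipeline",
    "PipelineStageError",
]


@dataclass
class PreprocessConfig:
    """Parameters for the six-stage enhancement pipeline.

    ``enhance_k`` is the detail-enhancement factor multiplying the summed
    top-hat differences; ``scales``/``weights`` are the four structuring
    element radii and their mixing weights.
    """

    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    median_kernel: int = 3
    gamma_bounds: tuple[float, float] = (0.5, 2.5)
    enhance_k: float = 1.0
    scales: tuple[int, ...] = (1, 2, 3, 4)
    weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 3")
        if len(self.scales) != 4 or len(self.weights) != 4:
            raise ValueError("exactly four scales and four weights are required")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be strictly increasing")
        if any(s <= 0 for s in self.scales):
            raise ValueError("structuring-element radii must be positive")
        lo, hi = self.gamma_bounds
        if not lo < hi:
            raise ValueError("gamma_bounds must satisfy lo < hi")


class PipelineStageError(RuntimeError):
    """Raised when a preprocessing stage fails; names the stage."""


def extract_green(img: FundusImage) -> np.ndarray:
    """Return the green channel (index 1) unchanged."""
    return img.pixels[:, :, 1].astype(np.float64)


def clahe(
    gray: np.ndarray, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a 0-255 grid.

    A zero-contrast (constant) input has nothing to equalize and is
    returned unchanged. ``clip`` follows the common integer convention
    (2.0 by default) and is mapped onto the normalized clip limit of the
    underlying implementation.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if tiles[0] > h or tiles[1] > w:
        raise ValueError(f"tile grid {tiles} larger than image {gray.shape}")
    if gray.max() == gray.min():
        return gray.copy()
    kernel = (max(1, h // tiles[0]), max(1, w // tiles[1]))
    out = equalize_adapthist(
        gray / 255.0, kernel_size=kernel, clip_limit=clip / 100.0
    )
    return out * 255.0


def median_denoise(gray: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with reflect padding; kernel must be odd and >= 3."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 3, got {kernel}")
    return median_filter(np.asarray(gray, dtype=np.float64), size=kernel, mode="reflect")


def minmax_normalize(gray: np.ndarray) -> np.ndarray:
    """Affine rescale so min -> 0 and max -> 1.

    A constant grid is degenerate (max == min): it maps to all zeros and
    a warning is emitted.
    """
    gray = np.asarray(gray, dtype=np.float64)
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        warnings.warn("constant image: min-max normalization returns zeros", stacklevel=2)
        return np.zeros_like(gray)
    return (gray - lo) / (hi - lo)


def adaptive_gamma(
    u: np.ndarray, gamma_bounds: tuple[float, float] = (0.5, 2.5)
) -> np.ndarray:
    """Mean-anchored gamma correction: gamma = log(0.5)/log(mean(u)).

    Images darker than mid-gray get gamma < 1 (brightening); the exponent
    is clamped to ``gamma_bounds``. Degenerate means of 0 or 1 clamp to the
    nearest bound with a warning.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.min() < 0 or u.max() > 1:
        raise ValueError("adaptive_gamma expects values in [0, 1]")
    lo, hi = gamma_bounds
    m = float(u.mean())
    if m <= 0.0:
        warnings.warn("image mean is 0; gamma clamped to lower bound", stacklevel=2)
        gamma = lo
    elif m >= 1.0:
        warnings.warn("image mean is 1; gamma clamped to upper bound", stacklevel=2)
        gamma = hi
    else:
        gamma = float(np.clip(np.log(0.5) / np.log(m), lo, hi))
    return np.clip(u**gamma, 0.0, 1.0)


def multiscale_enhance(u: np.ndarray, cfg: PreprocessConfig, clip: bool = True) -> np.ndarray:
    """Multi-scale top-hat detail enhancement.

    Adds bright detail (white top-hats) and subtracts dark detail (black
    top-hats) over the four configured disk radii:

        f = u + k * sum_i w_i * (wth_i(u) - bth_i(u))

    then clips to [0, 1] unless ``clip`` is disabled (used when checking
    linearity in k).
    """
    u = np.asarray(u, dtype=np.float64)
    if any(r <= 0 for r in cfg.scales):
        raise ValueError("structuring-element radii must be positive")
    detail = np.zeros_like(u)
    for r, w in zip(cfg.scales, cfg.weights):
        fp = disk(int(r))
        detail += w * (white_tophat(u, fp) - black_tophat(u, fp))
    out = u + cfg.enhance_k * detail
    return np.clip(out, 0.0, 1.0) if clip else out


_STAGES = (
    "extract_green",
    "clahe",
    "median_denoise",
    "minmax_normalize",
    "adaptive_gamma",
    "multiscale_enhance",
)


def preprocess_pipeline(img: FundusImage, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Run stages (a)-(f) in order and return a unit image in [0, 1]."""
    cfg = cfg or PreprocessConfig()
    stage = _STAGES[0]
    try:
        x = extract_green(img)
        stage = _STAGES[1]
        x = clahe(x, cfg.clahe_clip, cfg.clahe_tiles)
        stage = _STAGES[2]
        x = median_denoise(x, cfg.median_kernel)
        stage = _STAGES[3]
        x = minmax_normalize(x)
        stage = _STAGES[4]
        x = adaptive_gamma(x, cfg.gamma_bounds)
        stage = _STAGES[5]
        x = multiscale_enhance(x, cfg)
    except Exception as exc:
        raise PipelineStageError(f"preprocessing stage '{stage}' failed: {exc}") from exc
    return x
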