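"""Whole-image segmentation by overlapping-patch prediction and averaging."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DenseUNet

__all__ = ["ProbabilityMap", "predict_image", "binarize"]


@dataclass
class ProbabilityMap:
    """Per-pixel vessel probabilities; zero outside the field of view."""

    values: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.fov_mask.shape:
            raise ValueError("values and fov_mask shapes must match")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _tile_starts(length: int, patch: int, stride: int) -> np.ndarray:
    if length == patch:
        return np.array([0])
    n = int(np.ceil((length - patch) / stride))
    return np.arange(n + 1) * stride


def predict_image(
    model: DenseUNet,
    u: np.ndarray,
    fov: np.ndarray | None = None,
    patch_size: int = 48,
    stride: int = 8,
    batch_size: int = 64,
) -> ProbabilityMap:
    """Predict vessel probability for every pixel of a unit image.

    The image is reflect-padded so a grid of ``patch_size`` tiles at the
    given ``stride`` covers it exactly; each pixel's probability is the
    mean over all tiles containing it. Pixels outside ``fov`` are zeroed.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if stride > patch_size:
        raise ValueError("stride must not exceed patch_size")
    u = np.asarray(u, dtype=np.float64)
    h, w = u.shape
    rs = _tile_starts(max(h, patch_size), patch_size, stride)
    cs = _tile_starts(max(w, patch_size), patch_size, stride)
    hp = int(rs[-1]) + patch_size
    wp = int(cs[-1]) + patch_size
    up = np.pad(u, ((0, hp - h), (0, wp - w)), mode="reflect")

    positions = [(r, c) for r in rs for c in cs]
    acc = np.zeros((hp, wp))
    cnt = np.zeros((hp, wp))
    was_training = model.training
    model.set_training(False)
    try:
        for start in range(0, len(positions), batch_size):
            chunk = positions[start : start + batch_size]
            xb = np.stack(
                [up[r : r + patch_size, c : c + patch_size] for r, c in chunk]
            )[:, None].astype(model.dtype)
            yb = model.forward(xb)[:, 0]
            for (r, c), pred in zip(chunk, yb):
                acc[r : r + patch_size, c : c + patch_size] += pred
                cnt[r : r + patch_size, c : c + patch_size] += 1
    finally:
        model.set_training(was_training)
    prob = (acc / cnt)[:h, :w]
    prob = np.clip(prob, 0.0, 1.0)
    if fov is None:
        fov = np.ones((h, w), dtype=np.uint8)
    fov = np.asarray(fov).astype(np.uint8)
    prob = prob * (fov > 0)
    return ProbabilityMap(values=prob, fov_mask=fov)


def binarize(pm: ProbabilityMap, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary in-FOV vessel mask."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return ((pm.values >= threshold) & (pm.fov_mask > 0)).astype(np.uint8)
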