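"""Synthetic fundus-like image generation with known vessel ground truth.

Images mimic the properties the segmentation pipeline is designed around:
darker-than-background vessels (width roughly 1-8 px) laid out as random
branching trees, a radial illumination gradient, additive Gaussian noise,
a circular field of view, and a vessel pixel fraction near 10% of the FOV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import FundusImage, LabelImage, write_mask

__all__ = [
    "SynthConfig",
    "SyntheticSample",
    "fov_circle",
    "generate_vessel_tree",
    "render_fundus",
    "generate_sample",
    "generate_dataset",
    "write_drive_layout",
]

_FOV_RADIUS_FRAC = 0.48
_STEP = 2.2
_HEADING_JITTER = 0.18
_TAPER_PER_STEP = 0.99
_MAX_STEPS = 400


def _tree_step_budget(cfg: SynthConfig, fov_area: int) -> int:
    """Cap total steps per tree so one tree adds at most ~15% of the
    target vessel mass; keeps small images from being overrun and bounds
    the recursive branching."""
    target_px = cfg.target_vessel_fraction * fov_area
    return max(20, int(0.15 * target_px / (_STEP * cfg.root_width)))


@dataclass(frozen=True)
class SynthConfig:
    height: int = 584
    width: int = 565
    n_trees: int = 4
    branch_prob: float = 0.10
    max_depth: int = 6
    root_width: float = 6.0
    width_decay: float = 0.8
    vessel_contrast: float = 55.0
    illum_strength: float = 0.35
    noise_sigma: float = 6.0
    target_vessel_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 48 or self.width < 48:
            raise ValueError("synthetic images must be at least 48x48")
        if not 0.0 < self.width_decay < 1.0:
            raise ValueError("width_decay must be in (0, 1)")
        for name in ("branch_prob", "target_vessel_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticSample:
    image: FundusImage
    vessels: LabelImage
    fov: np.ndarray
    seed: int


def fov_circle(height: int, width: int) -> np.ndarray:
    """Centered circular FOV mask of radius 0.48 * min(H, W)."""
    r = _FOV_RADIUS_FRAC * min(height, width)
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(np.uint8)


def _draw_disk(grid: np.ndarray, y: float, x: float, radius: float) -> None:
    h, w = grid.shape
    r = max(radius, 0.5)
    y0, y1 = int(max(0, np.floor(y - r))), int(min(h, np.ceil(y + r) + 1))
    x0, x1 = int(max(0, np.floor(x - r))), int(min(w, np.ceil(x + r) + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid[y0:y1, x0:x1] |= ((yy - y) ** 2 + (xx - x) ** 2 <= r**2).astype(np.uint8)


def _grow_tree(
    grid: np.ndarray,
    fov: np.ndarray,
    rng: np.random.Generator,
    y: float,
    x: float,
    heading: float,
    width: float,
    depth: int,
    cfg: SynthConfig,
    budget: list[int],
) -> None:
    h, w = grid.shape
    steps = 0
    while width >= 1.0 and steps < _MAX_STEPS and budget[0] > 0:
        heading += rng.normal(0.0, _HEADING_JITTER)
        y += _STEP * np.sin(heading)
        x += _STEP * np.cos(heading)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < h and 0 <= ix < w) or not fov[iy, ix]:
            return
        _draw_disk(grid, y, x, width / 2.0)
        width *= _TAPER_PER_STEP
        steps += 1
        budget[0] -= 1
        if depth < cfg.max_depth and rng.random() < cfg.branch_prob:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            child_heading = heading + sign * rng.uniform(0.4, 1.0)
            _grow_tree(
                grid, fov, rng, y, x, child_heading, width * cfg.width_decay, depth + 1, cfg, budget
            )
            heading -= sign * rng.uniform(0.1, 0.3)


def _seed_tree(grid: np.ndarray, fov: np.ndarray, rng: np.random.Generator, cfg: SynthConfig) -> None:
    h, w = grid.shape
    r = _FOV_RADIUS_FRAC * min(h, w)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    angle = rng.uniform(0.0, 2.0 * np.pi)
    y = cy + (r - 2.0) * np.sin(angle)
    x = cx + (r - 2.0) * np.cos(angle)
    heading = angle + np.pi + rng.uniform(-0.4, 0.4)  # point inward
    budget = _tree_step_budget(cfg, int(fov.sum()))
    _grow_tree(grid, fov, rng, y, x, heading, cfg.root_width, 0, cfg, [budget])


def generate_vessel_tree(cfg: SynthConfig, seed: int) -> np.ndarray:
    """Rasterize ``cfg.n_trees`` random branching vessel trees as a binary grid.

    Each tree starts at the FOV boundary heading inward; segments advance
    with small random heading changes, spawn children with probability
    ``branch_prob`` at ``width_decay`` times the parent width, and stop
    when the width tapers below 1 px or the walk leaves the FOV.
    """
    grid = np.zeros((cfg.height, cfg.width), dtype=np.uint8)
    fov = fov_circle(cfg.height, cfg.width)
    rng = np.random.default_rng(seed)
    for _ in range(cfg.n_trees):
        _seed_tree(grid, fov, rng, cfg)
    return grid & fov


def render_fundus(vessels: np.ndarray, cfg: SynthConfig, seed: int) -> FundusImage:
    """Render a vessel grid into a color fundus-like image.

    Green channel = background level x radial illumination field, minus
    ``vessel_contrast`` on vessel pixels, plus Gaussian noise; red/blue
    are correlated lower-contrast copies. Before noise, the set of
    darkened pixels coincides exactly with the vessel grid.
    """
    h, w = vessels.shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = _FOV_RADIUS_FRAC * min(h, w)
    dist2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
    illum = 1.0 - cfg.illum_strength * np.minimum(dist2, 1.5)
    green = 170.0 * illum - cfg.vessel_contrast * (vessels > 0)
    if cfg.noise_sigma > 0:
        green = green + rng.normal(0.0, cfg.noise_sigma, size=green.shape)
    red = 0.55 * green + 60.0
    blue = 0.35 * green + 20.0
    pixels = np.clip(np.stack([red, green, blue], axis=-1), 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, image_id=f"synth{seed}", fov_mask=fov_circle(h, w))


def generate_sample(cfg: SynthConfig, seed: int) -> SyntheticSample:
    """Generate one image/label/FOV triple near the target vessel fraction.

    Trees are added (beyond ``cfg.n_trees``) until the in-FOV vessel
    fraction reaches 85% of ``target_vessel_fraction``, so every sample
    lands within a factor of two of the target.
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, render_seed, topup_seed = (int(s.generate_state(1)[0]) for s in ss.spawn(3))
    fov = fov_circle(cfg.height, cfg.width)
    fov_px = int(fov.sum())
    grid = generate_vessel_tree(cfg, tree_seed)
    rng = np.random.default_rng(topup_seed)
    extra = 0
    while grid.sum() / fov_px < 0.85 * cfg.target_vessel_fraction and extra < 200:
        _seed_tree(grid, fov, rng, cfg)
        grid &= fov
        extra += 1
    image = render_fundus(grid, cfg, render_seed)
    label = LabelImage(vessels=grid, image_id=image.image_id)
    return SyntheticSample(image=image, vessels=label, fov=fov, seed=seed)


def generate_dataset(n_images: int, cfg: SynthConfig, seed: int | None = None) -> list[SyntheticSample]:
    """Generate ``n_images`` reproducible samples with derived per-image seeds."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    master = cfg.seed if seed is None else seed
    child_seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(master).spawn(n_images)]
    samples = []
    for i, s in enumerate(child_seeds):
        sample = generate_sample(cfg, s)
        sample.image.image_id = f"{i + 1:02d}"
        sample.vessels.image_id = f"{i + 1:02d}"
        samples.append(sample)
    return samples


def write_drive_layout(samples: list[SyntheticSample], subset_dir: str | Path) -> None:
    """Write samples under ``subset_dir`` as images/, 1st_manual/, mask/ PNGs."""
    import imageio.v3 as iio

    subset_dir = Path(subset_dir)
    for sub in ("images", "1st_manual", "mask"):
        (subset_dir / sub).mkdir(parents=True, exist_ok=True)
    for s in samples:
        sid = s.image.image_id
        iio.imwrite(subset_dir / "images" / f"{sid}_image.png", s.image.pixels)
        write_mask(s.vessels.vessels, subset_dir / "1st_manual" / f"{sid}_manual1.png")
        write_mask(s.fov, subset_dir / "mask" / f"{sid}_mask.png")
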