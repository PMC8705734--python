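"""Random square patch extraction for training-set amplification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchSet", "sample_patches", "split_train_val"]


@dataclass
class PatchSet:
    """Aligned image/label patches with provenance.

    ``patches[i]`` and ``labels[i]`` are crops taken at identical
    coordinates from the image whose id is ``source_ids[i]``.
    """

    patches: np.ndarray  # (N, ps, ps) float32 in [0, 1]
    labels: np.ndarray  # (N, ps, ps) uint8 in {0, 1}
    source_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if self.patches.shape != self.labels.shape:
            raise ValueError("patches and labels must have identical shapes")
        if len(self.source_ids) != len(self.patches):
            raise ValueError("source_ids must align with patches")
        if len(self.patches) == 0:
            raise ValueError("a PatchSet must contain at least one patch")

    def __len__(self) -> int:
        return len(self.patches)


def sample_patches(
    images: list[np.ndarray],
    labels: list[np.ndarray],
    n_total: int = 190_000,
    patch_size: int = 48,
    seed: int = 0,
    source_ids: list[str] | None = None,
) -> PatchSet:
    """Draw ``n_total`` random patches, allocated equally across images.

    Patch centers are uniform over all positions at which the patch lies
    fully inside the image (equivalently, top-left corners are uniform on
    the valid grid). No FOV restriction and no class balancing: centers
    are purely random.
    """
    if len(images) == 0 or len(images) != len(labels):
        raise ValueError("need equal, non-empty image and label lists")
    n_images = len(images)
    if n_total <= 0 or n_total % n_images != 0:
        raise ValueError(
            f"n_total ({n_total}) must be a positive multiple of the image count ({n_images})"
        )
    per_image = n_total // n_images
    if source_ids is None:
        source_ids = [str(i) for i in range(n_images)]

    patches = np.empty((n_total, patch_size, patch_size), dtype=np.float32)
    out_labels = np.empty((n_total, patch_size, patch_size), dtype=np.uint8)
    ids: list[str] = []
    rng = np.random.default_rng(seed)
    pos = 0
    for img, lab, sid in zip(images, labels, source_ids):
        h, w = img.shape
        if lab.shape != (h, w):
            raise ValueError(f"image/label shape mismatch for source {sid}")
        if patch_size > h or patch_size > w:
            raise ValueError(
                f"patch_size {patch_size} exceeds image dims {h}x{w} (source {sid})"
            )
        rows = rng.integers(0, h - patch_size + 1, size=per_image)
        cols = rng.integers(0, w - patch_size + 1, size=per_image)
        for r, c in zip(rows, cols):
            patches[pos] = img[r : r + patch_size, c : c + patch_size]
            out_labels[pos] = lab[r : r + patch_size, c : c + patch_size]
            pos += 1
        ids.extend([sid] * per_image)
    return PatchSet(patches=patches, labels=out_labels, source_ids=ids, seed=seed)


def split_train_val(
    ps: PatchSet, val_fraction: float, seed: int = 0
) -> tuple[PatchSet, PatchSet]:
    """Shuffle and partition a PatchSet into disjoint train/validation sets."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    n = len(ps)
    n_train = int(round(n * (1.0 - val_fraction)))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    tr, va = perm[:n_train], perm[n_train:]

    def subset(idx: np.ndarray) -> PatchSet:
        return PatchSet(
            patches=ps.patches[idx],
            labels=ps.labels[idx],
            source_ids=[ps.source_ids[i] for i in idx],
            seed=ps.seed,
        )

    return subset(tr), subset(va)
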