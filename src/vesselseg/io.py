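"""Reading and writing fundus images, vessel masks and patch caches.

Conventions: arrays are row-major, 0-based, indexed (row, col). Color
images are ``(H, W, 3)`` uint8; masks are ``(H, W)`` uint8 in {0, 1}.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FundusImage",
    "LabelImage",
    "read_fundus",
    "read_label",
    "write_mask",
    "load_drive_split",
    "save_patch_cache",
    "load_patch_cache",
]

MIN_SIZE = 48

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".gif", ".ppm", ".jpg", ".jpeg")


@dataclass
class FundusImage:
    """A color fundus photograph with an optional field-of-view mask."""

    pixels: np.ndarray
    image_id: str
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"fundus pixels must be (H, W, 3), got {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < MIN_SIZE or w < MIN_SIZE:
            raise ValueError(f"image must be at least {MIN_SIZE}x{MIN_SIZE}, got {h}x{w}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask)
            if self.fov_mask.shape != (h, w):
                raise ValueError(
                    f"fov_mask shape {self.fov_mask.shape} != image shape {(h, w)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelImage:
    """Binary vessel annotation paired with a fundus image."""

    vessels: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        self.vessels = np.asarray(self.vessels)
        vals = np.unique(self.vessels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label values must be binary 0/1, found {vals}")
        self.vessels = self.vessels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessels.shape


def _image_id_from_path(path: Path) -> str:
    m = re.match(r"(\d+)", path.stem)
    return m.group(1) if m else path.stem


def _imread(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return np.asarray(arr)


def read_fundus(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/GIF fundus photograph as a 3-channel image.

    Grayscale files are replicated to three channels with a warning.
    """
    path = Path(path)
    arr = _imread(path)
    if arr.ndim == 2:
        warnings.warn(
            f"{path.name}: grayscale input replicated to 3 channels", stacklevel=2
        )
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"cannot interpret {path} as a color image (shape {arr.shape})")
    return FundusImage(pixels=arr.astype(np.uint8), image_id=_image_id_from_path(path))


def read_label(path: str | Path) -> LabelImage:
    """Read a vessel/FOV mask; values above 50% of the maximum map to 1."""
    path = Path(path)
    arr = _imread(path)
    if arr.ndim == 3:
        # palette/RGB encodings of a binary mask must be channel-identical
        if not (arr == arr[:, :, :1]).all():
            raise ValueError(f"{path}: color mask is not channel-uniform")
        arr = arr[:, :, 0]
    distinct = np.unique(arr)
    if distinct.size > 2:
        raise ValueError(
            f"{path}: mask has {distinct.size} distinct values {distinct[:5]}..., "
            "expected at most 2"
        )
    if distinct.size == 1 and distinct[0] == 0:
        binary = np.zeros(arr.shape, dtype=np.uint8)
    else:
        binary = (arr > 0.5 * arr.max()).astype(np.uint8)
    return LabelImage(vessels=binary, image_id=_image_id_from_path(path))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary grid as a lossless 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary 0/1, found values {vals}")
    path = Path(path)
    try:
        iio.imwrite(path, (mask * 255).astype(np.uint8), extension=".png")
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def _scan_dir(d: Path) -> dict[str, Path]:
    files = {}
    for p in sorted(d.iterdir()):
        if p.suffix.lower() in _IMAGE_EXTS:
            files[_image_id_from_path(p)] = p
    return files


def _load_pairs(subdir: Path) -> list[tuple[FundusImage, LabelImage]]:
    images_dir = subdir / "images"
    labels_dir = subdir / "1st_manual"
    masks_dir = subdir / "mask"
    for d in (images_dir, labels_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"expected DRIVE-layout directory {d}")
    images = _scan_dir(images_dir)
    labels = _scan_dir(labels_dir)
    fovs = _scan_dir(masks_dir) if masks_dir.is_dir() else {}
    orphans = sorted(set(images) ^ set(labels))
    if not images:
        raise FileNotFoundError(f"no images found under {images_dir}")
    if orphans:
        raise ValueError(
            f"unpaired image/label ids in {subdir}: {', '.join(orphans)}"
        )
    pairs = []
    for image_id in sorted(images):
        img = read_fundus(images[image_id])
        img.image_id = image_id
        if image_id in fovs:
            img.fov_mask = read_label(fovs[image_id]).vessels
        lab = read_label(labels[image_id])
        lab.image_id = image_id
        if lab.shape != img.shape:
            raise ValueError(
                f"{image_id}: label shape {lab.shape} != image shape {img.shape}"
            )
        pairs.append((img, lab))
    return pairs


def load_drive_split(
    root_dir: str | Path,
) -> tuple[list[tuple[FundusImage, LabelImage]], list[tuple[FundusImage, LabelImage]]]:
    """Load ``training/`` and ``test/`` image/label pairs from a DRIVE-layout tree.

    Each subset directory must contain ``images/`` and ``1st_manual/``
    (plus optional ``mask/`` FOV masks). Pairs are matched on the leading
    digits of the file name and returned sorted by image id.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    train = _load_pairs(root / "training")
    test = _load_pairs(root / "test")
    return train, test


def save_patch_cache(patch_set, path: str | Path) -> None:
    """Persist a :class:`~vesselseg.sampler.PatchSet` to an NPZ container.

    Dataset names are fixed: ``patches``, ``labels``, ``meta``.
    """
    meta = json.dumps({"source_ids": list(patch_set.source_ids), "seed": patch_set.seed})
    np.savez_compressed(
        path,
        patches=patch_set.patches.astype(np.float32),
        labels=patch_set.labels.astype(np.uint8),
        meta=np.array(meta),
    )


def load_patch_cache(path: str | Path):
    from .sampler import PatchSet

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no patch cache at {path}")
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return PatchSet(
            patches=z["patches"],
            labels=z["labels"],
            source_ids=list(meta["source_ids"]),
            seed=int(meta["seed"]),
        )
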