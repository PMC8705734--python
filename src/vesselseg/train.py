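"""Mini-batch SGD training of the segmentation network on patch sets."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .losses import batch_dice_loss
from .model import DenseUNet, NetworkSpec, build_network
from .sampler import PatchSet

__all__ = [
    "TrainConfig",
    "TrainLog",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    checkpoint_dir: str | None = None
    val_fraction: float = 0.1
    loss_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float


@dataclass
class TrainLog:
    records: list[EpochRecord] = field(default_factory=list)
    wall_seconds: float = 0.0

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,val_loss,val_dice"]
        for r in self.records:
            lines.append(f"{r.epoch},{r.train_loss:.6f},{r.val_loss:.6f},{r.val_dice:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _evaluate(model: DenseUNet, ps: PatchSet, batch_size: int, eps: float) -> tuple[float, float]:
    model.set_training(False)
    losses, dices, weights = [], [], []
    for start in range(0, len(ps), batch_size):
        xb = ps.patches[start : start + batch_size][:, None].astype(model.dtype)
        gb = ps.labels[start : start + batch_size][:, None].astype(np.float64)
        yb = model.forward(xb)
        loss, _ = batch_dice_loss(yb, gb, eps=eps)
        losses.append(loss)
        dices.append(1.0 - loss)
        weights.append(len(xb))
    model.set_training(True)
    w = np.asarray(weights, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(dices, weights=w))


def train(
    model: DenseUNet,
    train_set: PatchSet,
    val_set: PatchSet,
    cfg: TrainConfig,
) -> tuple[DenseUNet, TrainLog]:
    """Optimize the Dice loss with momentum SGD over shuffled mini-batches.

    The best-validation-Dice checkpoint is written to ``cfg.checkpoint_dir``
    (as ``best.npz``) when a directory is configured. Batch order is
    reshuffled every epoch from ``cfg.seed``; a NaN loss aborts with a
    diagnostic naming the epoch and batch.
    """
    log = TrainLog()
    if cfg.epochs == 0:
        return model, log
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
    best_dice = -np.inf
    ckpt_path = None
    if cfg.checkpoint_dir is not None:
        ckpt_dir = Path(cfg.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = ckpt_dir / "best.npz"
    t0 = time.time()
    model.set_training(True)
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(len(train_set))
        epoch_losses = []
        for bi, start in enumerate(range(0, len(perm), cfg.batch_size)):
            idx = perm[start : start + cfg.batch_size]
            xb = train_set.patches[idx][:, None].astype(model.dtype)
            gb = train_set.labels[idx][:, None].astype(np.float64)
            yb = model.forward(xb)
            loss, grad = batch_dice_loss(yb, gb, eps=cfg.loss_eps)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {bi}"
                )
            opt.zero_grad()
            model.backward(grad.astype(model.dtype))
            opt.step()
            epoch_losses.append(loss)
        val_loss, val_dice = _evaluate(model, val_set, cfg.batch_size, cfg.loss_eps)
        log.records.append(
            EpochRecord(epoch, float(np.mean(epoch_losses)), val_loss, val_dice)
        )
        if val_dice > best_dice:
            best_dice = val_dice
            if ckpt_path is not None:
                save_checkpoint(model, ckpt_path)
    log.wall_seconds = time.time() - t0
    return model, log


def save_checkpoint(model: DenseUNet, path: str | Path) -> None:
    """Write model weights plus the embedded NetworkSpec to an NPZ file."""
    state = model.state_dict()
    np.savez(path, __spec__=np.array(model.spec.to_json()), **state)


def load_checkpoint(path: str | Path, expected_spec: NetworkSpec | None = None) -> DenseUNet:
    """Rebuild a model from a checkpoint; error on a spec mismatch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    with np.load(path, allow_pickle=False) as z:
        spec = NetworkSpec.from_json(str(z["__spec__"]))
        if expected_spec is not None and spec != expected_spec:
            raise ValueError(
                f"checkpoint spec {spec} does not match expected spec {expected_spec}"
            )
        model = build_network(spec)
        state = {k: z[k] for k in z.files if k != "__spec__"}
    model.load_state_dict(state)
    return model
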