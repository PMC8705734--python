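"""Confusion counts, Acc/Sp/Sn/PPV ratios, and masked ROC/AUC.

All quantities are computed over in-FOV pixels only, with vessel as the
positive class. This follows the DRIVE evaluation convention; including
the uninformative pixels outside the field of view would inflate both
accuracy and specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricBundle",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricBundle:
    acc: float
    sp: float
    sn: float
    ppv: float
    auc: float


def _check_shapes(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among inputs: {sorted(shapes)}")


def confusion(pred: np.ndarray, gold: np.ndarray, fov: np.ndarray | None = None) -> ConfusionCounts:
    """Count TP/TN/FP/FN over in-FOV pixels (vessel = positive)."""
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if fov is None:
        fov = np.ones_like(gold)
    fov = np.asarray(fov)
    _check_shapes(pred, gold, fov)
    m = fov > 0
    p = pred[m] > 0
    g = gold[m] > 0
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """Accuracy, specificity, sensitivity and positive predictive value.

    Acc = (TP+TN)/(TP+FP+TN+FN), Sp = TN/(FP+TN), Sn = TP/(TP+FN),
    PPV = TP/(TP+FP). A zero denominator yields NaN with a warning.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (c.tp + c.tn) / c.total
    sp = _ratio(c.tn, c.fp + c.tn, "specificity")
    sn = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV")
    return acc, sp, sn, ppv


def roc_auc(
    prob: np.ndarray, gold: np.ndarray, fov: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve over all distinct in-FOV thresholds and trapezoidal AUC.

    Tied scores step the curve once per distinct value, so the trapezoid
    rule awards 0.5 credit per tied positive/negative pair and the AUC
    equals the Mann-Whitney pair-concordance statistic.

    Returns ``(fpr, tpr, auc)``.
    """
    prob = np.asarray(prob, dtype=np.float64)
    gold = np.asarray(gold)
    if fov is None:
        fov = np.ones_like(gold)
    fov = np.asarray(fov)
    _check_shapes(prob, gold, fov)
    m = fov > 0
    scores = prob[m].ravel()
    labels = (gold[m].ravel() > 0).astype(np.int64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative pixel in the FOV")
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    # keep the last index of each tie group (threshold steps once per distinct value)
    last_of_group = np.r_[scores[1:] != scores[:-1], True]
    tps = tps[last_of_group]
    fps = fps[last_of_group]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_segmentation(
    prob: np.ndarray,
    pred: np.ndarray,
    gold: np.ndarray,
    fov: np.ndarray | None = None,
) -> dict:
    """Bundle counts and all five metrics into a JSON-serializable dict."""
    c = confusion(pred, gold, fov)
    acc, sp, sn, ppv = metrics(c)
    _, _, auc = roc_auc(prob, gold, fov)
    return {
        "acc": acc,
        "sp": sp,
        "sn": sn,
        "ppv": ppv,
        "auc": auc,
        "counts": asdict(c),
    }
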