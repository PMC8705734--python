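"""Soft Dice coefficient, its analytic gradient, and the derived loss.

For predictions p in [0,1]^N and binary ground truth g:

    D(p, g) = (2 * sum(p*g) + eps) / (sum(p^2) + sum(g^2) + eps)

and, writing num = 2*sum(p*g) + eps and den = sum(p^2) + sum(g^2) + eps,

    dD/dp_j = (2*g_j*den - 2*p_j*num) / den^2

which reduces to the unsmoothed analytic form when eps = 0. The training
loss is 1 - D; its gradient is the negated Dice gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_coefficient", "dice_gradient", "dice_loss", "dice_loss_gradient"]


def _validate(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p has {p.size} elements, g has {g.size}")
    if p.size == 0:
        raise ValueError("operands must contain at least one element")
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("ground truth must be strictly binary {0, 1}")
    return p, g


def dice_coefficient(p: np.ndarray, g: np.ndarray, eps: float = 0.0) -> float:
    """Soft Dice overlap in [0, 1]; 1 means perfect binary agreement."""
    p, g = _validate(p, g)
    num = 2.0 * float(p @ g) + eps
    den = float(p @ p) + float(g @ g) + eps
    if den == 0.0:
        raise ZeroDivisionError("Dice denominator is zero; use eps > 0 for empty operands")
    return num / den


def dice_gradient(p: np.ndarray, g: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Analytic gradient dD/dp_j of the (optionally smoothed) Dice coefficient."""
    p, g = _validate(p, g)
    num = 2.0 * float(p @ g) + eps
    den = float(p @ p) + float(g @ g) + eps
    if den == 0.0:
        raise ZeroDivisionError("Dice denominator is zero; use eps > 0 for empty operands")
    return (2.0 * g * den - 2.0 * p * num) / den**2


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1.0) -> float:
    """Training loss 1 - D(p, g); 0 for a perfect prediction."""
    return 1.0 - dice_coefficient(p, g, eps=eps)


def dice_loss_gradient(p: np.ndarray, g: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Gradient of the Dice loss: the negated Dice gradient."""
    return -dice_gradient(p, g, eps=eps)


def batch_dice_loss(
    p: np.ndarray, g: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Per-patch Dice loss averaged over the batch, with its gradient.

    ``p`` and ``g`` are (B, ...) arrays; the Dice coefficient is computed
    per patch and the loss is ``mean_b (1 - D_b)``. Returns the scalar
    loss and the gradient with respect to ``p`` (same shape as ``p``).
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("batch shapes must match")
    b = p.shape[0]
    pf = p.reshape(b, -1)
    gf = g.reshape(b, -1)
    inter = (pf * gf).sum(axis=1)
    num = 2.0 * inter + eps
    den = (pf**2).sum(axis=1) + (gf**2).sum(axis=1) + eps
    d = num / den
    loss = float(np.mean(1.0 - d))
    grad = -(2.0 * gf * den[:, None] - 2.0 * pf * num[:, None]) / den[:, None] ** 2 / b
    return loss, grad.reshape(p.shape)
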