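"""Training losses: soft Dice for segmentation, scaled MSE for regression."""

from __future__ import annotations

import numpy as np

__all__ = [
    "dice_loss", "dice_loss_with_grad",
    "scaled_mse_loss", "scaled_mse_loss_with_grad",
]

_EPS = 1e-8


def _as_batched(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 4:
        a = a[None]
    if a.ndim != 5:
        raise ValueError(f"expected (C,x,y,z) or (B,C,x,y,z), got {a.shape}")
    return a


def dice_loss_with_grad(pred_probs, target_onehot):
    """Soft Dice loss and its gradient w.r.t. the predicted probabilities.

    ``1 - mean_c (2 sum(p_c t_c)) / (sum(p_c^2) + sum(t_c^2))``, averaged
    over classes (and the batch).  Zero exactly when the prediction equals
    the one-hot target; 1 when supports are disjoint.
    """
    p = _as_batched(pred_probs)
    t = _as_batched(target_onehot)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if p[0, 0].size == 0:
        raise ValueError("empty volume")
    axes = (2, 3, 4)
    inter = (p * t).sum(axis=axes)
    denom = (p * p).sum(axis=axes) + (t * t).sum(axis=axes) + _EPS
    dice = 2.0 * inter / denom
    loss = 1.0 - dice.mean()
    # d(dice_c)/dp = (2 t * denom - 2 inter * 2 p) / denom^2
    coef = 1.0 / (dice.size)
    grad = -coef * (2.0 * t * denom[..., None, None, None]
                    - 4.0 * inter[..., None, None, None] * p) \
        / denom[..., None, None, None] ** 2
    if np.asarray(pred_probs).ndim == 4:
        grad = grad[0]
    return float(loss), grad


def dice_loss(pred_probs, target_onehot) -> float:
    """Soft Dice loss (see :func:`dice_loss_with_grad`)."""
    return dice_loss_with_grad(pred_probs, target_onehot)[0]


def scaled_mse_loss_with_grad(pred_map, target_density, scale: float = 10000.0):
    """Mean square error against ``scale * target`` and its gradient.

    The centroid density target has unit-height peaks on a sea of zeros;
    multiplying it by a large factor during training keeps the network from
    collapsing to the all-zero prediction.
    """
    p = np.asarray(pred_map, dtype=np.float64)
    t = np.asarray(target_density, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    resid = p - scale * t
    loss = float(np.mean(resid ** 2))
    grad = 2.0 * resid / resid.size
    return loss, grad


def scaled_mse_loss(pred_map, target_density, scale: float = 10000.0) -> float:
    return scaled_mse_loss_with_grad(pred_map, target_density, scale)[0]
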