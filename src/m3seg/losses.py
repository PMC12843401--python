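"""Compound segmentation objective: cross-entropy + Dice.

``total = lambda_ce * CE + lambda_dice * Dice`` with both weights 0.5 by
default. Cross-entropy gives smooth per-pixel classification gradients;
the Dice term directly optimises overlap and counters the class imbalance
of small foreground structures (class 0, the background, is excluded from
its average).

All three losses accept either autodiff :class:`~m3seg.autodiff.Tensor`
probability maps (for training) or plain numpy arrays (returning floats).
Probability maps are laid out ``(..., C, H, W)`` or ``(N, C)``; the ground
truth is one-hot with the same layout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .config import ConfigurationError, LossConfig

__all__ = ["one_hot", "ce_loss", "dice_loss", "total_loss", "LossConfig"]

_P_FLOOR = 1e-12  # clamp for log; keeps CE finite for exact-zero probabilities


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer mask (..., H, W) -> one-hot (..., C, H, W)."""
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError(f"mask labels must lie in [0, {num_classes})")
    eye = np.eye(num_classes)
    return np.moveaxis(eye[mask], -1, mask.ndim - 2)


def _as_tensor(p):
    return p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))


def _channel_axis(p) -> int:
    # (N, C) layouts use axis -1; image layouts (..., C, H, W) use axis -3
    return -1 if p.ndim == 2 else -3


def ce_loss(p, y):
    """Mean cross-entropy: ``-(1/N) sum_i sum_c y_ic log p_ic``.

    N is the number of pixels (classes are summed, not averaged).
    """
    was_array = not isinstance(p, Tensor)
    pt = _as_tensor(p)
    yd = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    if pt.shape != yd.shape:
        raise ValueError(f"probability map {pt.shape} and target {yd.shape} differ")
    n_pixels = pt.size // pt.shape[_channel_axis(pt)]
    loss = -(Tensor(yd) * pt.clip_min(_P_FLOOR).log()).sum() * (1.0 / n_pixels)
    return loss.item() if was_array else loss


def dice_loss(p, y, cfg: LossConfig | None = None):
    """Soft Dice loss averaged over the C-1 foreground classes.

    ``1 - (1/(C-1)) sum_{c>=1} 2 sum_i p_ic y_ic / (sum_i p_ic + sum_i y_ic)``
    with the smoothing constant added to numerator and denominator.
    """
    cfg = cfg or LossConfig()
    was_array = not isinstance(p, Tensor)
    pt = _as_tensor(p)
    yd = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    if pt.shape != yd.shape:
        raise ValueError(f"probability map {pt.shape} and target {yd.shape} differ")
    ax = _channel_axis(pt)
    C = pt.shape[ax]
    start = 1 if cfg.background_excluded else 0
    if C - start < 1:
        raise ConfigurationError("dice_loss needs at least one foreground class")
    # flatten to (C, n) with pixels on the last axis
    if ax == -1:
        pc = pt.swapaxes(0, 1)
        yc = np.swapaxes(yd, 0, 1)
    else:
        pc = pt.swapaxes(0, pt.ndim + ax).reshape(C, -1)
        yc = np.swapaxes(yd, 0, yd.ndim + ax).reshape(C, -1)
    pc = pc.reshape(C, -1)[start:]
    yc = yc.reshape(C, -1)[start:]
    inter = (pc * Tensor(yc)).sum(axis=1)
    sums = pc.sum(axis=1) + Tensor(yc.sum(axis=1))
    dice = (inter * 2.0 + cfg.smooth) / (sums + cfg.smooth)
    loss = 1.0 - dice.mean()
    return loss.item() if was_array else loss


def total_loss(p, y, cfg: LossConfig | None = None):
    """Weighted compound loss ``lambda_ce * CE + lambda_dice * Dice``."""
    cfg = cfg or LossConfig()
    return cfg.lambda_ce * ce_loss(p, y) + cfg.lambda_dice * dice_loss(p, y, cfg)
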