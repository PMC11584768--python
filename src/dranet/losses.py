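"""Compound segmentation loss: 0.5 * BCE + soft Dice.

BCE supplies a well-scaled per-pixel gradient early in training; the soft
Dice term is invariant to foreground size and dominates once predictions
sharpen.  Both operate on probability maps (post-sigmoid) against binary
targets.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import InvalidInputError
from .nn import F, Tensor

__all__ = ["bce_loss", "dice_loss", "total_loss"]

_EPS = 1e-7


def _pair(pred, target) -> tuple[Tensor, Tensor]:
    p = nn.as_tensor(pred)
    t = nn.as_tensor(target)
    if p.shape != t.shape:
        raise InvalidInputError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return p, t


def bce_loss(pred, target, weights=None) -> Tensor:
    """Mean binary cross entropy, predictions clipped to (eps, 1-eps).

    ``weights`` optionally rescales each element's contribution (default 1).
    """
    p, t = _pair(pred, target)
    p = F.clip(p, _EPS, 1.0 - _EPS)
    ll = t * F.log(p) + (1.0 - t) * F.log(1.0 - p)
    if weights is not None:
        ll = ll * nn.as_tensor(weights)
    return -F.mean(ll)


def dice_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss ``1 - (2*sum(xy)+smooth) / (sum(x)+sum(y)+smooth)``
    over all pixels; ``smooth`` stabilizes empty masks (use ~0 for metric
    cross-checks)."""
    p, t = _pair(pred, target)
    inter = F.sum_(p * t)
    denom = F.sum_(p) + F.sum_(t)
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def total_loss(pred, target, bce_weight: float = 0.5, smooth: float = 1.0) -> Tensor:
    """The training objective: ``0.5 * BCE + Dice``."""
    return bce_weight * bce_loss(pred, target) + dice_loss(pred, target, smooth=smooth)
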