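"""Training losses: soft Dice, binary cross-entropy, and their hybrid.

The hybrid loss is ``L = alpha * Dice + (1 - alpha) * BCE``, the usual
remedy for extreme foreground/background imbalance in nodule masks: the
Dice term is scale-free in the foreground size while BCE keeps per-pixel
gradients well conditioned early in training.

All three accept either plain NumPy arrays or autodiff tensors; with
tensors the returned scalar participates in backpropagation.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

#: smoothing added to the Dice numerator and denominator
DICE_EPS = 1e-6
#: probabilities are clipped to [BCE_CLIP, 1 - BCE_CLIP] before the log
BCE_CLIP = 1e-7


def _check_shapes(probs, target) -> None:
    ps = probs.shape if isinstance(probs, Tensor) else np.shape(probs)
    ts = target.shape if isinstance(target, Tensor) else np.shape(target)
    if ps != ts:
        raise ValueError(f"probability/target shape mismatch: {ps} vs {ts}")


def soft_dice_loss(probs, target, eps: float = DICE_EPS) -> Tensor:
    """``1 - (2 Σ p·t + eps) / (Σ p + Σ t + eps)`` over all pixels.

    On hard (binary) ``probs`` with ``eps=0`` this equals ``1 - DSC``
    computed from the confusion counts.
    """
    _check_shapes(probs, target)
    p = as_tensor(probs)
    t = as_tensor(target)
    inter = (p * t).sum()
    denom = p.sum() + t.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def bce_loss(probs, target, clip: float = BCE_CLIP) -> Tensor:
    """Mean binary cross-entropy ``-[t log p + (1-t) log(1-p)]``."""
    _check_shapes(probs, target)
    p = as_tensor(probs)
    t = as_tensor(target)
    p = _clip(p, clip)
    term = t * ad.log(p) + (1.0 - t) * ad.log(1.0 - p)
    return -term.mean()


def _clip(p: Tensor, clip: float) -> Tensor:
    clipped = np.clip(p.data, clip, 1.0 - clip)
    out = Tensor(clipped, parents=(p,))
    inside = (p.data > clip) & (p.data < 1.0 - clip)

    def backward(g):
        if p.requires_grad:
            p._accumulate(g * inside)

    out._backward = backward
    return out


def hybrid_loss(probs, target, alpha: float = 0.5) -> Tensor:
    """Convex combination ``alpha * Dice + (1 - alpha) * BCE``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * soft_dice_loss(probs, target) + (1.0 - alpha) * bce_loss(probs, target)
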