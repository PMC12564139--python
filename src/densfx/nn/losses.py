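"""Task losses with analytic gradients: class-weighted cross-entropy for
classification and the combined soft-Dice + cross-entropy loss for
segmentation."""
from __future__ import annotations

import numpy as np

from .autograd import Tensor, _accum, _node
from ..errors import DimensionError

__all__ = [
    "softmax",
    "soft_dice",
    "cross_entropy_loss",
    "dice_ce_loss",
    "compute_class_weights",
]

_EPS = 1e-7


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def soft_dice(p_fg: np.ndarray, target: np.ndarray, eps: float = _EPS) -> float:
    """Soft Dice between foreground probabilities and a binary target."""
    s = float((p_fg * target).sum())
    return (2.0 * s + eps) / (float(p_fg.sum()) + float(target.sum()) + eps)


def compute_class_weights(n_per_class) -> np.ndarray:
    """Inverse-prevalence weights w_c = N / (K * N_c); their prevalence-
    weighted mean is 1."""
    counts = np.asarray(n_per_class, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError(f"all class counts must be > 0, got {tuple(n_per_class)}")
    return counts.sum() / (counts.size * counts)


def cross_entropy_loss(logits: Tensor, labels: np.ndarray, class_weights=None) -> Tensor:
    """Weighted mean cross-entropy over (N, K) logits."""
    y = np.asarray(labels).astype(int)
    if logits.data.shape[0] != y.size:
        raise DimensionError("logits / labels length mismatch")
    k = logits.data.shape[1]
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    p = softmax(logits.data)
    wy = w[y]
    wsum = wy.sum()
    loss = float(-(wy * np.log(p[np.arange(y.size), y] + _EPS)).sum() / wsum)

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[np.arange(y.size), y] = 1.0
        _accum(logits, g * wy[:, None] * (p - onehot) / wsum)

    return _node(np.asarray(loss), (logits,), backward)


def dice_ce_loss(
    logits: Tensor,
    target: np.ndarray,
    dice_weight: float = 0.5,
    ce_weight: float = 0.5,
    class_weights=None,
) -> Tensor:
    """w_d * (1 - soft Dice) + w_ce * weighted per-voxel cross-entropy.

    ``logits`` is (N, 2, D, H, W); ``target`` a binary (N, D, H, W) mask.
    """
    t = np.asarray(target, dtype=np.float64)
    if logits.data.shape[0] != t.shape[0] or logits.data.shape[2:] != t.shape[1:]:
        raise DimensionError(
            f"prediction {logits.data.shape} does not match target {t.shape}"
        )
    if dice_weight < 0 or ce_weight < 0 or dice_weight + ce_weight == 0:
        raise ValueError("loss weights must be >= 0 and not both zero")
    w = np.ones(2) if class_weights is None else np.asarray(class_weights, dtype=np.float64)

    p = softmax(logits.data, axis=1)
    p1 = p[:, 1]
    ssum = float((p1 * t).sum())
    den = float(p1.sum() + t.sum()) + _EPS
    dice = (2.0 * ssum + _EPS) / den
    l_dice = 1.0 - dice

    wv = np.where(t > 0.5, w[1], w[0])
    wsum = float(wv.sum())
    pt = np.where(t > 0.5, p1, p[:, 0])
    l_ce = float(-(wv * np.log(pt + _EPS)).sum() / wsum)
    loss = dice_weight * l_dice + ce_weight * l_ce

    def backward(g):
        # dice term: dL/dp1, then chain through the channel softmax
        dldp1 = -(2.0 * t / den - (2.0 * ssum + _EPS) / den**2)
        grad = np.zeros_like(logits.data)
        for c in range(2):
            ind = 1.0 if c == 1 else 0.0
            grad[:, c] += dice_weight * dldp1 * p1 * (ind - p[:, c])
        # cross-entropy term: w (p - onehot) / wsum per voxel
        tgt = np.stack([1.0 - t, t], axis=1)
        grad += ce_weight * wv[:, None] * (p - tgt) / wsum
        _accum(logits, g * grad)

    return _node(np.asarray(loss), (logits,), backward)
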