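"""Dice-based training losses.

Multi-label segmentation of small structures against a dominant background
biases likelihood losses toward predicting background everywhere.  The
Dice-hinge loss counters this: for every foreground class the soft Dice
loss ``1 − 2Σpt/(Σp + Σt)`` is computed, classes already fitted better
than a hinge margin are clamped to zero contribution, and the remaining
(active) foreground classes are averaged.  Well-fitted classes thus stop
pulling on the shared softmax, concentrating the gradient on classes still
in error.  Setting ``hinge_margin = 0`` recovers the plain mean
foreground soft-Dice loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "dice_hinge_loss", "soft_dice_per_class", "one_hot", "hard_dice"]

_EPS = 1e-6


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(B, X, Y, Z) integer labels -> (B, n_classes, X, Y, Z) float32 one-hot."""
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels outside [0, {n_classes}): found {labels.min()}..{labels.max()}"
        )
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    b = np.arange(labels.shape[0])[:, None, None, None]
    x, y, z = np.indices(labels.shape[1:])
    out[b, labels, x[None], y[None], z[None]] = 1.0
    return out


def soft_dice_per_class(probs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-class soft Dice pooled over batch and voxels; shape (n_classes,)."""
    axes = (0, 2, 3, 4)
    inter = (probs * target).sum(axis=axes, dtype=np.float64)
    denom = probs.sum(axis=axes, dtype=np.float64) + target.sum(axis=axes, dtype=np.float64)
    return ((2.0 * inter + _EPS) / (denom + _EPS)).astype(np.float64)


def dice_hinge_loss(probs: np.ndarray, target: np.ndarray, hinge_margin: float = 0.1):
    """Dice-hinge loss and its gradient with respect to the probabilities.

    ``probs`` and one-hot ``target`` are (B, C, X, Y, Z); class 0 is
    background and excluded from the loss.  Per foreground class c the soft
    Dice loss ``1 − D_c`` is clamped to 0 when below ``hinge_margin``; the
    loss is the mean over the unclamped classes (0.0 when every class is
    clamped).  Returns ``(loss, dloss_dprobs)``.
    """
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    axes = (0, 2, 3, 4)
    inter = (probs * target).sum(axis=axes, dtype=np.float64)
    psum = probs.sum(axis=axes, dtype=np.float64)
    tsum = target.sum(axis=axes, dtype=np.float64)
    denom = psum + tsum + _EPS
    dice = (2.0 * inter + _EPS) / denom
    loss_c = 1.0 - dice
    fg = np.arange(1, probs.shape[1])
    active = fg[loss_c[fg] > hinge_margin]
    dprobs = np.zeros_like(probs)
    if active.size == 0:
        return 0.0, dprobs
    loss = float(loss_c[active].mean())
    scale = 1.0 / active.size
    for c in active:
        # d(1-D_c)/dp_c = -(2 t * denom - (2 I + eps)) / denom^2
        num = 2.0 * inter[c] + _EPS
        g = -(2.0 * target[:, c] * denom[c] - num) / (denom[c] ** 2)
        dprobs[:, c] = scale * g
    return loss, dprobs


def dlogits_from_dprobs(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Chain rule through the softmax: dL/dz = p * (dL/dp − Σ_c p_c dL/dp_c)."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return (probs * (dprobs - inner)).astype(probs.dtype)


def hard_dice(pred_labels: np.ndarray, true_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-foreground-class hard Dice; nan for classes absent from both."""
    out = np.full(n_classes - 1, np.nan)
    for c in range(1, n_classes):
        p = pred_labels == c
        t = true_labels == c
        denom = p.sum() + t.sum()
        if denom > 0:
            out[c - 1] = 2.0 * np.logical_and(p, t).sum() / denom
    return out
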