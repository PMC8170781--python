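"""Tversky loss on per-pixel class probabilities.

The Tversky index generalises Dice overlap with asymmetric weights on
false positives (alpha) and false negatives (beta); alpha = beta = 0.5
recovers the soft Dice coefficient exactly.  Counts are soft (summed
probabilities) and pooled over all pixels of the batch; the loss is the
mean over classes of (1 - TI_c), hence bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TverskyConfig", "tversky_loss", "tversky_loss_and_grad", "one_hot", "softmax"]


@dataclass
class TverskyConfig:
    """alpha weights false positives, beta false negatives; the defaults
    (0.3, 0.7) penalise missed cell pixels more than spurious ones."""

    alpha: float = 0.3
    beta: float = 0.7
    smooth: float = 1e-6

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.smooth < 0:
            raise ValueError("smooth must be non-negative")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(..., H, W) int labels -> (..., C, H, W) one-hot floats."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _soft_counts(pred: np.ndarray, target: np.ndarray, class_axis: int = 1):
    axes = tuple(a for a in range(pred.ndim) if a != class_axis % pred.ndim)
    tp = (pred * target).sum(axis=axes)
    fp = (pred * (1.0 - target)).sum(axis=axes)
    fn = ((1.0 - pred) * target).sum(axis=axes)
    return tp, fp, fn


def tversky_loss(pred: np.ndarray, target: np.ndarray, cfg: TverskyConfig | None = None) -> float:
    """Mean over classes of 1 - (TP+s) / (TP + a*FP + b*FN + s).

    ``pred`` holds per-pixel class probabilities (N, C, H, W) summing to 1
    over the class axis; ``target`` is the matching one-hot encoding.
    """
    cfg = cfg or TverskyConfig()
    cfg.validate()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    tp, fp, fn = _soft_counts(pred, target)
    ti = (tp + cfg.smooth) / (tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth)
    return float(np.mean(1.0 - ti))


def tversky_loss_and_grad(pred: np.ndarray, target: np.ndarray, cfg: TverskyConfig, class_axis: int = 1):
    """Loss and its gradient with respect to the probabilities."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    tp, fp, fn = _soft_counts(pred, target, class_axis)
    num = tp + cfg.smooth
    den = tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth
    loss = float(np.mean(1.0 - num / den))
    n_classes = pred.shape[class_axis]
    shape = [1] * pred.ndim
    shape[class_axis % pred.ndim] = n_classes
    num_b = num.reshape(shape)
    den_b = den.reshape(shape)
    # d(1-TI)/dp = -(t*D - T*(t + a*(1-t) - b*t)) / D^2, averaged over classes
    dcount = target + cfg.alpha * (1.0 - target) - cfg.beta * target
    grad = -(target * den_b - num_b * dcount) / (den_b**2) / n_classes
    return loss, grad
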