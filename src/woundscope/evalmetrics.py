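"""Segmentation and counting evaluation: IoU, boundary F1, count
comparison and relative errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

__all__ = ["iou", "boundary_f1", "count_comparison", "relative_error", "CountComparison"]


def iou(pred: np.ndarray, gt: np.ndarray, n_classes: int | None = None):
    """Intersection over union (Jaccard index), per class and mean.

    Binary masks give a single float; label maps give (per_class, mean)
    where the per-class vector covers classes 0..n_classes-1.  A class
    empty in both masks scores 1.0 (prevents spurious zeros on
    background-only tiles).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    if pred.dtype == bool or n_classes is None and pred.max(initial=0) <= 1 and gt.max(initial=0) <= 1:
        a = pred.astype(bool)
        b = gt.astype(bool)
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 1.0
        return float(np.logical_and(a, b).sum() / union)
    if n_classes is None:
        n_classes = int(max(pred.max(), gt.max())) + 1
    per_class = np.empty(n_classes)
    for c in range(n_classes):
        per_class[c] = iou(pred == c, gt == c)
    return per_class, float(per_class.mean())


def _boundary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=1)
    return mask & ~eroded


def boundary_f1(pred: np.ndarray, gt: np.ndarray, tolerance_px: float | None = None) -> float:
    """Boundary overlap F1: precision/recall of boundary pixels matched
    within a Euclidean tolerance (default 0.75% of the image diagonal)."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    if tolerance_px is None:
        tolerance_px = 0.0075 * float(np.hypot(*pred.shape))
    if tolerance_px < 0:
        raise ValueError("tolerance must be non-negative")
    bp = _boundary(pred)
    bg = _boundary(gt)
    if not bp.any() and not bg.any():
        return 1.0
    if not bp.any() or not bg.any():
        return 0.0
    dist_to_gt = ndi.distance_transform_edt(~bg)
    dist_to_pred = ndi.distance_transform_edt(~bp)
    precision = float((dist_to_gt[bp] <= tolerance_px).mean())
    recall = float((dist_to_pred[bg] <= tolerance_px).mean())
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class CountComparison:
    mean_a: float
    mean_b: float
    differences: np.ndarray
    p_value: float | None


def count_comparison(counts_a, counts_b) -> CountComparison:
    """Compare per-frame cell counts of two methods.

    Returns the means, the per-frame differences and the two-sided paired
    t-test p-value (undefined with fewer than 2 frames or constant
    differences)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same length")
    diffs = a - b
    p: float | None
    if a.size < 2 or np.allclose(diffs, diffs[0]):
        p = None
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return CountComparison(float(a.mean()), float(b.mean()), diffs, p)


def relative_error(candidate, reference):
    """|candidate - reference| / |reference|, elementwise.

    Scalars give a float; sequences give (per-element array, mean over the
    elements with non-zero reference).  Zero references yield NaN entries
    (flagged undefined) that are excluded from the mean.
    """
    c = np.asarray(candidate, dtype=float)
    r = np.asarray(reference, dtype=float)
    if c.shape != r.shape:
        raise ValueError("shape mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(c - r) / np.abs(r)
    err = np.where(r == 0, np.nan, err)
    if err.ndim == 0:
        return float(err)
    finite = err[np.isfinite(err)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return err, mean
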