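"""Segmentation agreement scores and the slice-continuity statistic.

Precision, recall, F1 and IoU compare binary voxel masks, optionally
inside an evaluation mask (e.g. the border-exclusion region).  The
slice-continuity statistic is the variance of IoU between consecutive
xy-slices of a segmentation: a smooth, consistent segmentation of a
slowly varying 3D object has nearly constant neighbour IoU, so low
variance, while jittery single-view 2D inference has high variance.

Empty-denominator conventions (needed for empty phantom slices):
precision and recall are 1 when their denominator is 0, F1(empty, empty)
is 1, and IoU(empty, empty) is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "precision_recall_f1",
    "iou",
    "iou_smoothness",
]


def _as_bool(x) -> np.ndarray:
    if isinstance(x, LabelVolume):
        return x.binary()
    return np.asarray(x).astype(bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level TP/FP/FN/TN under an evaluation mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred, truth, eval_mask=None) -> ConfusionCounts:
    """Count TP/FP/FN/TN between binary masks, restricted to ``eval_mask``.

    A 2D ``eval_mask`` (e.g. from ``edge_exclusion_mask``) is broadcast
    over all slices of 3D inputs.
    """
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape}, truth {t.shape}")
    if eval_mask is not None:
        m = np.asarray(eval_mask).astype(bool)
        if m.ndim == p.ndim - 1:
            m = np.broadcast_to(m, p.shape)
        if m.shape != p.shape:
            raise ValueError(f"eval_mask shape {m.shape} incompatible with {p.shape}")
        p, t = p[m], t[m]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = harmonic mean of the two."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 1.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def iou(a, b) -> float:
    """Intersection over union of two binary masks; IoU(empty, empty) = 1."""
    pa, pb = _as_bool(a), _as_bool(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    union = int(np.count_nonzero(pa | pb))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(pa & pb)) / union


def iou_smoothness(
    labels, start_pair: int = 0, n_pairs: int = 5, population: bool = True
) -> float:
    """Variance of IoU between consecutive xy-slices — a smoothness score.

    ``IoU_k = iou(slice_k, slice_{k+1})`` for ``k`` in
    ``[start_pair, start_pair + n_pairs - 1]``; the (population, by
    default) variance of these ``n_pairs`` values is returned.
    ``start_pair`` selects the pair window, so windows such as pairs
    [2, 6] and [3, 7] are both expressible.

    Every slice in the window must contain foreground; the first empty
    slice otherwise aborts with an error naming it.
    """
    arr = _as_bool(labels)
    if arr.ndim != 3:
        raise ValueError("iou_smoothness expects a 3D stack")
    last = start_pair + n_pairs
    if last > arr.shape[0] - 1:
        raise ValueError(f"need slices up to {last}, volume has only {arr.shape[0]}")
    for z in range(start_pair, last + 1):
        if not arr[z].any():
            raise ValueError(f"slice {z} contains no foreground")
    series = np.array([iou(arr[k], arr[k + 1]) for k in range(start_pair, last)])
    return float(np.var(series, ddof=0 if population else 1))
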