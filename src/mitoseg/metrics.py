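"""Confusion-count and Jaccard (IoU) metrics, plus ground-truth tolerance.

Foreground IoU is ``TP / (TP + FP + FN)`` with foreground as the positive
class; background IoU swaps the classes; overall IoU is their plain mean.
Probability maps are binarised at 0.5 upstream.  When a union is empty the
score is defined as 1 if both masks are empty and 0 if exactly one is (the
convention needed for averaging over background-only patches).

``perturbation_tolerance`` measures how far the scores of a dataset's own
annotations move under a 1-pixel morphological dilation/erosion — an
estimate of the annotation noise floor against which model differences
should be judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "IoUReport",
    "confusion_counts",
    "iou",
    "iou_from_counts",
    "perturbation_tolerance",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class IoUReport:
    foreground: float
    background: float

    @property
    def overall(self) -> float:
        return (self.foreground + self.background) / 2.0


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred > 0, truth > 0


def confusion_counts(pred, truth) -> ConfusionCounts:
    p, t = _check_binary_pair(pred, truth)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _jaccard(tp: int, fp: int, fn: int) -> float:
    union = tp + fp + fn
    if union == 0:
        return 1.0
    return tp / union


def iou_from_counts(c: ConfusionCounts) -> IoUReport:
    return IoUReport(
        foreground=_jaccard(c.tp, c.fp, c.fn),
        background=_jaccard(c.tn, c.fn, c.fp),
    )


def iou(pred, truth) -> IoUReport:
    """Foreground/background/overall IoU of two binary volumes."""
    return iou_from_counts(confusion_counts(pred, truth))


def _structure(ndim: int, mode: str) -> np.ndarray:
    """1-pixel structuring element: 3x3 square in-plane; optionally 3D cube."""
    if mode == "2d":
        if ndim == 2:
            return np.ones((3, 3), dtype=bool)
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1] = True
        return s
    if mode == "3d":
        return np.ones((3,) * ndim, dtype=bool)
    raise ValueError("mode must be '2d' or '3d'")


def perturbation_tolerance(
    truth, radius: int = 1, mode: str = "2d"
) -> tuple[float, float]:
    """Foreground IoU of dilated and eroded ground truth against itself.

    ``mode='2d'`` (default) perturbs per slice with a 3x3 square element,
    matching per-slice expert annotations; ``mode='3d'`` uses a cube.
    Returns ``(iou_dilated, iou_eroded)``.
    """
    t = np.asarray(truth) > 0
    if radius < 1:
        raise ValueError("radius must be >= 1")
    struct = _structure(t.ndim, mode)
    dil = ndimage.binary_dilation(t, struct, iterations=radius)
    ero = ndimage.binary_erosion(t, struct, iterations=radius)
    iou_dil = iou(dil, t).foreground
    if t.any() and not ero.any():
        warnings.warn("erosion removed all foreground; iou_eroded = 0", stacklevel=2)
        iou_ero = 0.0
    else:
        iou_ero = iou(ero, t).foreground
    return iou_dil, iou_ero
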