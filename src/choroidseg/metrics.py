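"""Segmentation evaluation: region overlap metrics, boundary extraction from
binary masks, and the surface metrics AUSDE and thickness difference.

AUSDE (average unsigned surface detection error) is the mean per-column
absolute row difference between a predicted and a true boundary; the
thickness difference TD is the mean per-column absolute difference between
predicted and true choroidal thickness (CSI minus BM row).  Columns where a
boundary is missing in either trace are excluded from the averages and their
count reported, so methods that fail to form a continuous boundary are
measurable rather than undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trace import BoundaryTrace

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "region_metrics",
    "extract_boundaries",
    "ausde",
    "thickness_difference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return mask.astype(bool)


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/TN/FN between two binary masks."""
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return ConfusionCounts(tp, fp, tn, fn)


def region_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Dice, IoU, accuracy and sensitivity from confusion counts.

    Zero denominators yield 0 with a warning, except the degenerate case of
    an empty ground truth matched by an empty prediction, where overlap
    metrics are 1 by convention.
    """

    def ratio(num: int, den: int, name: str, empty_match: bool) -> float:
        if den == 0:
            if empty_match:
                return 1.0
            warnings.warn(f"zero denominator for {name}; returning 0")
            return 0.0
        return num / den

    empty_match = c.tp + c.fp + c.fn == 0
    return {
        "dice": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dice", empty_match),
        "iou": ratio(c.tp, c.tp + c.fp + c.fn, "iou", empty_match),
        "acc": ratio(c.tp + c.tn, c.total, "acc", False),
        "sen": ratio(c.tp, c.tp + c.fn, "sen", c.tp + c.fn == 0 and c.fp == 0),
    }


def extract_boundaries(mask, keep_largest: bool = True) -> BoundaryTrace:
    """Trace BM and CSI from a binary choroid mask.

    Optionally keeps only the largest 4-connected foreground component, then
    per column takes BM as the topmost foreground row and CSI as the
    bottommost foreground row + 1 (half-open convention, matching the
    synthetic renderer).  Columns without foreground are NaN.
    """
    m = _check_binary(mask, "mask")
    if not m.any():
        warnings.warn("empty mask: returning all-missing trace")
        nan = np.full(m.shape[1], np.nan)
        return BoundaryTrace(nan, nan)
    if keep_largest:
        labels, n = ndimage.label(m)  # 4-connectivity by default
        if n > 1:
            sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
            m = labels == (int(np.argmax(sizes)) + 1)
    h, w = m.shape
    rows = np.arange(h)[:, None]
    any_fg = m.any(axis=0)
    bm = np.where(any_fg, np.where(m, rows, h).min(axis=0), np.nan)
    csi = np.where(any_fg, np.where(m, rows, -1).max(axis=0) + 1.0, np.nan)
    return BoundaryTrace(bm.astype(float), csi.astype(float))


def _joint(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    pred, gt = np.asarray(pred, float), np.asarray(gt, float)
    if pred.shape != gt.shape:
        raise ValueError("boundary arrays must share their width")
    return np.isfinite(pred) & np.isfinite(gt)


def ausde(pred_rows, gt_rows, return_coverage: bool = False):
    """Average unsigned surface detection error in pixels.

    Mean of |pred - gt| over columns where both are defined; with
    ``return_coverage`` also returns the fraction of jointly defined
    columns.
    """
    ok = _joint(pred_rows, gt_rows)
    if not ok.any():
        raise ValueError("no column where both boundaries are defined")
    err = float(np.mean(np.abs(np.asarray(pred_rows, float)[ok]
                               - np.asarray(gt_rows, float)[ok])))
    if return_coverage:
        return err, float(ok.mean())
    return err


def thickness_difference(pred: BoundaryTrace, gt: BoundaryTrace,
                         return_coverage: bool = False):
    """Mean absolute difference between predicted and true choroidal
    thickness (pixels), over columns where both traces are complete."""
    ok = pred.valid & gt.valid
    if pred.width != gt.width:
        raise ValueError("traces must share their width")
    if not ok.any():
        raise ValueError("no column where both traces are complete")
    td = float(np.mean(np.abs(np.abs(pred.thickness_px()[ok])
                              - np.abs(gt.thickness_px()[ok]))))
    if return_coverage:
        return td, float(ok.mean())
    return td
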