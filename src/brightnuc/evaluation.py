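"""Pixel-wise and object-wise segmentation metrics.

Object-level scoring is existence-based: a ground-truth nucleus counts as
detected at an IoU threshold if *some* predicted object overlaps it with
IoU >= threshold (no one-to-one assignment); predicted objects that detect
nothing at the threshold are false positives.  The object F1 is reported
at thresholds 0.50-0.95 (step 0.05) and averaged.  The error taxonomy
counts merges (a predicted object overlapping >= 2 ground-truth nuclei at
IoU >= 0.1), splits (the mirror case), and missed nuclei (best IoU < 0.6).
Every IoU gate uses the >= convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

OBJECT_F1_THRESHOLDS = np.round(np.arange(0.50, 0.951, 0.05), 2)
MERGE_SPLIT_IOU = 0.1
MISSED_IOU = 0.6


# ---------------------------------------------------------------------------
# pixel metrics
# ---------------------------------------------------------------------------

@dataclass
class PixelMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    balanced_accuracy: float


def pixel_metrics(pred: np.ndarray, gt: np.ndarray) -> PixelMetrics:
    """Confusion counts and derived rates for binary foreground masks.

    Balanced accuracy is the mean of sensitivity and specificity.  The F1
    of an empty prediction against an empty ground truth is defined as 1.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
    accuracy = (tp + tn) / pred.size
    tnr = tn / (tn + fp) if tn + fp else 1.0
    balanced = (recall + tnr) / 2
    return PixelMetrics(tp, fp, fn, tn, precision, recall, f1,
                        accuracy, balanced)


# ---------------------------------------------------------------------------
# object matching
# ---------------------------------------------------------------------------

@dataclass
class MatchTable:
    """All-pairs IoU between ground-truth and predicted objects."""

    iou: np.ndarray        # K_gt x K_pred
    areas_gt: np.ndarray   # K_gt
    areas_pred: np.ndarray  # K_pred

    @property
    def n_gt(self) -> int:
        return self.iou.shape[0]

    @property
    def n_pred(self) -> int:
        return self.iou.shape[1]


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> MatchTable:
    """All-pairs IoU in one joint-histogram pass over the two label maps."""
    gt = np.asarray(gt).astype(np.int64)
    pred = np.asarray(pred).astype(np.int64)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch {gt.shape} vs {pred.shape}")
    kg, kp = int(gt.max()), int(pred.max())
    joint = np.bincount(gt.ravel() * (kp + 1) + pred.ravel(),
                        minlength=(kg + 1) * (kp + 1)).reshape(kg + 1, kp + 1)
    inter = joint[1:, 1:].astype(np.float64)
    areas_gt = joint[1:, :].sum(axis=1)
    areas_pred = joint[:, 1:].sum(axis=0)
    union = areas_gt[:, None] + areas_pred[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return MatchTable(iou=iou, areas_gt=areas_gt, areas_pred=areas_pred)


def object_f1(mt: MatchTable, threshold: float) -> float:
    """Existence-based object detection F1 at one IoU threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    if mt.n_gt == 0 and mt.n_pred == 0:
        return 1.0
    if mt.n_gt == 0 or mt.n_pred == 0:
        return 0.0
    tp = int((mt.iou.max(axis=1) >= threshold).sum())
    fn = mt.n_gt - tp
    fp = int((mt.iou.max(axis=0) < threshold).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def count_merges_splits(mt: MatchTable,
                        threshold: float = MERGE_SPLIT_IOU) -> tuple[int, int]:
    """Merge/split events at a low IoU gate (one event per offending object).

    A merge is a predicted object overlapping >= 2 ground-truth nuclei at
    IoU >= threshold; a split is a ground-truth nucleus overlapped by >= 2
    predictions.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    hits = mt.iou >= threshold
    merges = int((hits.sum(axis=0) >= 2).sum())
    splits = int((hits.sum(axis=1) >= 2).sum())
    return merges, splits


def count_missed(mt: MatchTable, threshold: float = MISSED_IOU) -> int:
    """Ground-truth nuclei whose best prediction IoU falls below threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    if mt.n_gt == 0:
        return 0
    if mt.n_pred == 0:
        return mt.n_gt
    return int((mt.iou.max(axis=1) < threshold).sum())


@dataclass
class ObjectReport:
    f1_at: dict
    f1_avg: float
    merges: int
    splits: int
    missed: int


def object_report(gt_labels: np.ndarray, pred_labels: np.ndarray) -> ObjectReport:
    """Object F1 over the 0.50-0.95 grid plus the error taxonomy."""
    mt = iou_matrix(gt_labels, pred_labels)
    f1_at = {float(t): object_f1(mt, float(t)) for t in OBJECT_F1_THRESHOLDS}
    merges, splits = count_merges_splits(mt)
    return ObjectReport(f1_at=f1_at,
                        f1_avg=float(np.mean(list(f1_at.values()))),
                        merges=merges, splits=splits,
                        missed=count_missed(mt))


# ---------------------------------------------------------------------------
# object-property and dataset-level analyses
# ---------------------------------------------------------------------------

def object_property_match(gt: np.ndarray, pred: np.ndarray,
                          iou_threshold: float = 0.5):
    """Paired (area, solidity) tables for objects matched at IoU >= 0.5.

    Solidity is area / convex-hull area.  Returns two records arrays with
    fields gt_area, pred_area, gt_solidity, pred_solidity, iou.
    """
    mt = iou_matrix(gt, pred)
    props_gt = {p.label: p for p in measure.regionprops(np.asarray(gt))}
    props_pred = {p.label: p for p in measure.regionprops(np.asarray(pred))}
    rows = []
    for i in range(mt.n_gt):
        j = int(mt.iou[i].argmax()) if mt.n_pred else -1
        if j < 0 or mt.iou[i, j] < iou_threshold:
            continue
        pg, pp = props_gt[i + 1], props_pred[j + 1]
        rows.append((pg.area, pp.area, pg.solidity, pp.solidity, mt.iou[i, j]))
    return np.array(rows, dtype=[("gt_area", float), ("pred_area", float),
                                 ("gt_solidity", float), ("pred_solidity", float),
                                 ("iou", float)])


def density_correlation(per_image) -> tuple[float, float]:
    """Pearson r and OLS slope of pixel F1 against nucleus count per image.

    ``per_image`` is a sequence of (n_objects_gt, f1).  With zero variance
    in either variable the correlation is undefined (NaN) and the slope is
    0 (or NaN when the counts are constant).
    """
    arr = np.asarray(list(per_image), dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 images")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    if np.ptp(y) == 0:
        return float("nan"), 0.0
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope


def size_decile_analysis(objects) -> dict:
    """Median object IoU per area decile.

    ``objects`` is a sequence of (area, iou) per ground-truth object.
    Returns {decile (1..10): median iou}; deciles are area-quantile bins.
    """
    arr = np.asarray(list(objects), dtype=float)
    if len(arr) < 10:
        raise ValueError("need at least 10 objects for a decile analysis")
    areas, ious = arr[:, 0], arr[:, 1]
    edges = np.quantile(areas, np.linspace(0, 1, 11))
    out = {}
    for d in range(10):
        lo, hi = edges[d], edges[d + 1]
        sel = (areas >= lo) & (areas <= hi if d == 9 else areas < hi)
        if not sel.any():  # duplicate quantile edges on tied areas
            sel = areas == lo
        out[d + 1] = float(np.median(ious[sel]))
    return out
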