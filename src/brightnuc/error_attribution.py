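"""Attribute segmentation errors to their likely sources.

Three procedures: (1) consensus-based label-noise estimation — pixels
where at least four of five models agree on a prediction opposite to the
ground truth are flagged as probable annotation noise, and reported as
the fraction of each model's misclassified pixels (averaged over models);
(2) artifact-region deltas — the share of error pixels inside manually
annotated anomalous regions, and the pixel-F1 gain from scoring outside
them only; (3) the false-negative / false-positive decomposition of the
error pixels.
"""

from __future__ import annotations

import json

import numpy as np
from skimage import draw

from .evaluation import pixel_metrics


def consensus_noise_fraction(model_masks, gt: np.ndarray,
                             min_agree: int = 4) -> float:
    """Fraction of misclassified pixels attributable to label noise.

    A pixel is flagged when >= ``min_agree`` of the models share the same
    prediction and it is opposite to the ground-truth label.  For each
    model the flagged share of its own error pixels is computed; the mean
    over models is returned.  Models without errors contribute 0.
    """
    masks = [np.asarray(m).astype(bool) for m in model_masks]
    if len(masks) < 5:
        raise ValueError(f"need >= 5 model masks, got {len(masks)}")
    gt = np.asarray(gt).astype(bool)
    for m in masks:
        if m.shape != gt.shape:
            raise ValueError("mask shape mismatch")
    votes_fg = np.sum(masks, axis=0)
    n = len(masks)
    # opposite-consensus: enough models say foreground where gt is
    # background, or background where gt is foreground
    flagged = np.where(gt, (n - votes_fg) >= min_agree, votes_fg >= min_agree)
    fractions = []
    for m in masks:
        err = m != gt
        n_err = int(err.sum())
        fractions.append((err & flagged).sum() / n_err if n_err else 0.0)
    return float(np.mean(fractions))


def fp_fn_decomposition(pred: np.ndarray, gt: np.ndarray):
    """(fn_fraction, fp_fraction) of the error pixels; NaN when error-free."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    fn = int((~pred & gt).sum())
    fp = int((pred & ~gt).sum())
    total = fn + fp
    if total == 0:
        return float("nan"), float("nan")
    return fn / total, fp / total


def artifact_delta(pred: np.ndarray, gt: np.ndarray, artifact: np.ndarray):
    """Error share inside artifact regions and the F1 gain outside them.

    Returns (error_fraction_in_artifact, f1_outside_minus_overall).  The
    first value is NaN when there are no error pixels; both are 0 for an
    empty artifact mask.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    artifact = np.asarray(artifact).astype(bool)
    if not (pred.shape == gt.shape == artifact.shape):
        raise ValueError("shape mismatch")
    err = pred != gt
    n_err = int(err.sum())
    frac_in = (err & artifact).sum() / n_err if n_err else float("nan")
    f1_all = pixel_metrics(pred, gt).f1
    keep = ~artifact
    f1_out = pixel_metrics(pred[keep], gt[keep]).f1
    return frac_in, f1_out - f1_all


def rasterize_artifact_polygons(polygons_json, shape) -> np.ndarray:
    """Binary artifact mask from a polygon JSON annotation.

    The JSON is either a list of polygons or {"polygons": [...]}, each
    polygon a list of [row, col] vertices.
    """
    if isinstance(polygons_json, str):
        data = json.loads(polygons_json)
    else:
        data = polygons_json
    if isinstance(data, dict):
        data = data["polygons"]
    mask = np.zeros(shape, dtype=bool)
    for poly in data:
        arr = np.asarray(poly, dtype=float)
        rr, cc = draw.polygon(arr[:, 0], arr[:, 1], shape=shape)
        mask[rr, cc] = True
    return mask
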