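"""Probability maps -> labeled nucleus objects.

The pipeline is: binarize at a 0.5 cutoff (foreground at p >= cutoff),
cluster interconnected positive pixels into 8-connected objects, remove
objects smaller than 25 pixels, and fill background holes smaller than
25 pixels.  Holes are detected with 4-connectivity (the complement
pairing of 8-connected objects).  Removal precedes filling and uses the
raw (pre-fill) areas, so an undersized object cannot be rescued by its
own filled hole; the combination is idempotent.  Labels are compacted to
1..K in raster order of each object's first pixel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology


def binarize(prob_map: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Boolean foreground mask: pixel positive iff p >= cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    return np.asarray(prob_map) >= cutoff


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Compact labels to 1..K ordered by each object's first raster pixel."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    first_seen = {}
    for v in flat[flat > 0]:
        if v not in first_seen:
            first_seen[v] = len(first_seen) + 1
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for old, new in first_seen.items():
        lut[old] = new
    return lut[labels]


def label_objects(mask: np.ndarray) -> np.ndarray:
    """8-connected components, labeled 1..K in raster order of first pixel."""
    lab = measure.label(np.asarray(mask).astype(bool), connectivity=2)
    return relabel_raster_order(lab)


def fill_small_holes(labels: np.ndarray, max_hole: int = 25) -> np.ndarray:
    """Fill 4-connected background holes with area < max_hole (strict).

    Filled pixels take the label of the enclosing object (the most common
    8-neighbor label around the hole).
    """
    labels = np.asarray(labels).astype(np.int32)
    binary = labels > 0
    filled = morphology.remove_small_holes(binary, connectivity=1,
                                           max_size=max_hole - 1)
    new_pixels = filled & ~binary
    if not new_pixels.any():
        return labels.copy()
    out = labels.copy()
    hole_lab, n_holes = ndimage.label(new_pixels)  # 4-connectivity default
    for h in range(1, n_holes + 1):
        region = hole_lab == h
        ring = ndimage.binary_dilation(
            region, structure=np.ones((3, 3), bool)) & ~region
        neighbor_labels = labels[ring]
        neighbor_labels = neighbor_labels[neighbor_labels > 0]
        if len(neighbor_labels):
            out[region] = np.bincount(neighbor_labels).argmax()
    return out


def filter_objects(labels: np.ndarray, min_area: int = 25,
                   max_hole: int = 25) -> np.ndarray:
    """Drop objects below min_area, then fill small holes; recompact."""
    out = np.asarray(labels).astype(np.int32).copy()
    areas = np.bincount(out.ravel())
    small = np.flatnonzero(areas[1:] < min_area) + 1 if len(areas) > 1 else []
    if len(small):
        out[np.isin(out, small)] = 0
    out = fill_small_holes(out, max_hole)
    return relabel_raster_order(out)


def postprocess(prob_map: np.ndarray, cutoff: float = 0.5,
                min_area: int = 25, max_hole: int = 25) -> np.ndarray:
    """Full pipeline: binarize -> label -> fill holes -> filter objects."""
    return filter_objects(label_objects(binarize(prob_map, cutoff)),
                          min_area=min_area, max_hole=max_hole)
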