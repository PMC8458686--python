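"""Image/mask I/O, dataset manifests and splits, patch tiling and stitching.

Images are grayscale TIFF (single- or multi-plane, up to 9 focal planes)
or PNG; probability maps are written as 32-bit float TIFF and label maps
as 16-bit integer TIFF.  A dataset manifest is a CSV with the header
``image,mask,cell_line,well,field,split`` mapping every field of view to
its ground-truth mask and experimental coordinates.

Conventions: 0-based, half-open windows, row-major offsets.  Tiling uses
an overlapping grid whose edge windows are shifted inward (never padded),
and stitching averages all patch predictions covering a pixel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MANIFEST_COLUMNS = ["image", "mask", "cell_line", "well", "field", "split"]
SPLITS = ("train", "val", "test")


@dataclass
class ImageStack:
    """One field of view: H x W x C float32 intensities (C focal planes)."""

    pixels: np.ndarray
    pixel_size_um: float = 0.59
    modality: str = "brightfield"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[..., None]
        h, w, c = self.pixels.shape
        if h < 32 or w < 32:
            raise ValueError(f"image too small: {h}x{w} (need >= 32)")
        if not 1 <= c <= 9:
            raise ValueError(f"plane count {c} outside [1, 9]")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite intensities")

    @property
    def planes(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self):
        return self.pixels.shape


def robust_normalize(pixels: np.ndarray) -> np.ndarray:
    """Affine rescale from the 1st-99th intensity percentiles to [0, 1].

    Values outside the percentile window are clipped; a constant image
    (zero dynamic range) maps to all zeros.  Robust to the bright outliers
    common in brightfield illumination.
    """
    arr = np.asarray(pixels, dtype=np.float32)
    lo, hi = np.percentile(arr, [1, 99])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def read_image(path, normalize: bool = False, modality: str = "brightfield",
               pixel_size_um: float = 0.59) -> ImageStack:
    """Read a grayscale TIFF or PNG (optionally multi-plane) as ImageStack."""
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read image {path!r}: {e}") from e
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 9:
        raise ValueError(f"expected grayscale image, got RGB(A): {path!r}")
    if arr.ndim == 3:
        # TIFF stacks are plane-major (C, H, W)
        arr = np.moveaxis(arr, 0, -1)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}: {path!r}")
    arr = arr.astype(np.float32)
    if normalize:
        arr = robust_normalize(arr)
    return ImageStack(arr, pixel_size_um=pixel_size_um, modality=modality)


def write_image(path, array: np.ndarray) -> None:
    """Write an image, preserving dtype (float32 TIFF for probability maps,
    uint16 TIFF for label maps, uint8/16 for raw intensities)."""
    path = os.fspath(path)
    arr = np.asarray(array)
    if arr.ndim == 3:  # H, W, C -> plane-major TIFF
        arr = np.moveaxis(arr, -1, 0)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# patch grids
# ---------------------------------------------------------------------------

def _axis_offsets(size: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)  # inward shift, never pad
    return starts


@dataclass
class PatchGrid:
    """Overlapping tiling of an H x W image with inward-shifted edges."""

    patch_size: int = 288
    stride: int = 288
    offsets: list = field(default_factory=list)

    @classmethod
    def for_shape(cls, shape, patch_size: int = 288, stride: int | None = None):
        h, w = shape[:2]
        if patch_size > min(h, w):
            raise ValueError(
                f"patch_size {patch_size} exceeds image {h}x{w}")
        stride = stride or patch_size
        offsets = [(r, c)
                   for r in _axis_offsets(h, patch_size, stride)
                   for c in _axis_offsets(w, patch_size, stride)]
        return cls(patch_size=patch_size, stride=stride, offsets=offsets)


def extract_patches(stack: ImageStack | np.ndarray, grid: PatchGrid):
    """Yield (patch_size x patch_size x C patch, (row, col)) per window."""
    pixels = stack.pixels if isinstance(stack, ImageStack) else np.asarray(stack)
    if pixels.ndim == 2:
        pixels = pixels[..., None]
    ps = grid.patch_size
    for r, c in grid.offsets:
        yield pixels[r:r + ps, c:c + ps], (r, c)


def stitch_predictions(patches, shape) -> np.ndarray:
    """Mean-blend overlapping patch predictions into a full-field map.

    ``patches`` is a sequence of (2-D array, (row, col)); every pixel of
    ``shape`` must be covered by at least one patch.
    """
    h, w = shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int32)
    for patch, (r, c) in patches:
        patch = np.asarray(patch)
        ph, pw = patch.shape[:2]
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            raise ValueError(f"patch at {(r, c)} exceeds bounds {h}x{w}")
        acc[r:r + ph, c:c + pw] += patch
        cnt[r:r + ph, c:c + pw] += 1
    if (cnt == 0).any():
        n = int((cnt == 0).sum())
        raise ValueError(f"{n} pixels not covered by any patch")
    return (acc / cnt).astype(np.float32)


def predict_full_field(net, image: np.ndarray, patch_size: int | None = None,
                       stride: int | None = None) -> np.ndarray:
    """Tile an image, run the network per patch, stitch the mean blend."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    ps = patch_size or net.spec.input_size
    ps = min(ps, *arr.shape[:2])
    grid = PatchGrid.for_shape(arr.shape, ps, stride or ps)
    preds = [(net.predict(patch), off) for patch, off in extract_patches(arr, grid)]
    return stitch_predictions(preds, arr.shape[:2])


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def validate_manifest(df: pd.DataFrame, check_paths: bool = False,
                      root: str = ".") -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    per_image = df.groupby("image")["split"].nunique()
    dup = per_image[per_image > 1]
    if len(dup):
        raise ValueError(f"images in multiple splits: {list(dup.index)[:5]}")
    bad = set(df["split"]) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown split values {sorted(bad)}")
    if check_paths:
        for col in ("image", "mask"):
            for p in df[col]:
                full = os.path.join(root, p)
                if not os.path.exists(full):
                    raise FileNotFoundError(f"manifest references missing {full}")
    return df


def read_manifest(path, check_paths: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    return validate_manifest(df, check_paths=check_paths,
                             root=os.path.dirname(os.fspath(path)))


def write_manifest(df: pd.DataFrame, path) -> None:
    validate_manifest(df)[MANIFEST_COLUMNS].to_csv(path, index=False)


def split_manifest(records, fractions=(2 / 3, 1 / 6, 1 / 6),
                   counts=None, seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits, deterministically under ``seed``.

    ``records`` is a DataFrame (or list of dicts) with at least the image
    and mask columns.  Either ``fractions`` (summing to 1; sizes match to
    +-1 record) or explicit ``counts`` per split may be given; with counts,
    leftover records go to the last nonzero-count split's complement only
    if counts sum to fewer than the records available, in which case the
    remainder is dropped into 'test'.
    """
    df = pd.DataFrame(records).copy()
    n = len(df)
    if n < 1:
        raise ValueError("no records to split")
    if counts is not None:
        if sum(counts) > n:
            raise ValueError(f"counts {counts} exceed {n} records")
        sizes = list(counts)
        sizes[2] += n - sum(counts)  # remainder held out as test
    else:
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if n < sum(1 for f in fractions if f > 0):
            raise ValueError(f"{n} records cannot fill all splits")
        sizes = [int(np.floor(f * n)) for f in fractions]
        i = 0
        while sum(sizes) < n:  # distribute remainder, earliest splits first
            sizes[i % 3] += 1
            i += 1
    order = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(SPLITS, sizes):
        split[order[start:start + size]] = name
        start += size
    df["split"] = split
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return validate_manifest(df[MANIFEST_COLUMNS])
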