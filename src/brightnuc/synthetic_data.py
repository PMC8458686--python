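"""Synthetic paired microscopy scenes for testing the segmentation stack.

Each scene is a triple (brightfield-like stack, fluorescence-like image,
ground-truth label map) with the statistical structure of high-content
nucleus imaging: several hundred elliptical nuclei per megapixel field,
variable size, low brightfield contrast (a dark rim around a faintly
brighter interior on a mid-gray background), additive noise, a fraction
of out-of-focus cells that are visible in fluorescence but blurred in
every brightfield plane, optional opaque contamination artifacts that
affect brightfield only, multi-plane focal stacks with blur growing with
distance from the focus plane, and an optional rigid spatial shift of the
ground truth relative to the brightfield render (emulating physical
nucleus movement between acquisition rounds).

The default configuration mirrors the regime of a 1080 x 1080 field at
0.59 um/pixel with ~353 nuclei; the ``lncap_like`` preset mirrors the
2556 x 2156 / ~681-nuclei regime.  The generator aims at controllable
difficulty, not photorealism.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from . import imaging_io

PRESETS = ("seven_line_like", "lncap_like", "density_sweep", "size_sweep",
           "focal_stack")

DENSITY_GRID = (50, 150, 300, 600)
SIZE_GRID = (6.0, 9.0, 12.0, 18.0)


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of one synthetic paired scene."""

    height: int = 1080
    width: int = 1080
    n_nuclei: int = 353
    radius_mean_px: float = 12.0
    radius_sd_px: float = 3.0
    eccentricity_max: float = 0.4
    min_center_spacing_px: float = 8.0
    contrast: float = 0.35
    noise_sd: float = 0.05
    cell_body_factor: float = 1.8
    cell_body_amp: float = 0.3
    out_of_focus_fraction: float = 0.1
    artifact: tuple | None = None  # (count, (r_min, r_max), opacity)
    n_planes: int = 1
    plane_blur_step: float = 1.5
    focus_plane: int | None = None  # defaults to the center plane
    modality_shift_px: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.radius_mean_px <= 1:
            raise ValueError("radius_mean_px must exceed 1")
        if not 0 <= self.eccentricity_max < 1:
            raise ValueError("eccentricity_max outside [0, 1)")
        for name in ("out_of_focus_fraction",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast outside (0, 1]")
        if not 1 <= self.n_planes <= 9:
            raise ValueError("n_planes outside [1, 9]")


@dataclass
class Scene:
    """One rendered field: ground truth, fluorescence, brightfield stack."""

    gt: np.ndarray             # H x W int32 label map
    fluorescence: np.ndarray   # H x W float32
    brightfield: np.ndarray    # H x W x n_planes float32
    artifact_mask: np.ndarray  # H x W bool
    nuclei: pd.DataFrame       # realized per-nucleus table
    config: SceneConfig


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_nuclei(config: SceneConfig) -> pd.DataFrame:
    """Dart-throwing placement of elliptical nuclei.

    Centers are uniform with a hard minimum spacing; major radii are
    normal(radius_mean, radius_sd) truncated to [2, mean + 3 sd]; minor
    radii shrink by a uniform eccentricity; orientation is uniform.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nuclei
    cols = ["cy", "cx", "r_major", "r_minor", "angle", "in_focus"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    centers = np.empty((0, 2))
    max_attempts = 10_000 * n
    attempts = 0
    spacing2 = config.min_center_spacing_px ** 2
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} nuclei with spacing "
                f"{config.min_center_spacing_px} in {config.height}x"
                f"{config.width}; lower the density or spacing")
        attempts += 1
        cand = rng.uniform([0, 0], [config.height, config.width])
        if len(centers) and (((centers - cand) ** 2).sum(axis=1) < spacing2).any():
            continue
        centers = np.vstack([centers, cand])
    lo, hi = 2.0, config.radius_mean_px + 3 * config.radius_sd_px
    r_major = np.clip(rng.normal(config.radius_mean_px, config.radius_sd_px, n),
                      lo, hi)
    ecc = rng.uniform(0, config.eccentricity_max, n)
    r_minor = np.maximum(r_major * (1 - ecc), lo)
    angle = rng.uniform(0, np.pi, n)
    in_focus = rng.random(n) >= config.out_of_focus_fraction
    return pd.DataFrame({"cy": centers[:, 0], "cx": centers[:, 1],
                         "r_major": r_major, "r_minor": r_minor,
                         "angle": angle, "in_focus": in_focus})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_pixels(cy, cx, r_major, r_minor, angle, shape):
    return draw.ellipse(cy, cx, r_minor, r_major, shape=shape, rotation=angle)


def _artifact_blobs(config: SceneConfig, rng) -> np.ndarray:
    """Well-separated irregular blobs; exactly ``count`` connected regions."""
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=bool)
    count, (r_min, r_max), _ = config.artifact
    centers = []
    sep = 2 * r_max + 6
    for _ in range(count):
        for _ in range(10_000):
            cy, cx = rng.uniform(r_max, h - r_max), rng.uniform(r_max, w - r_max)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= sep ** 2 for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError("could not place separated artifacts")
    for cy, cx in centers:
        for _ in range(3):  # union of jittered disks -> irregular outline
            r = rng.uniform(r_min, r_max)
            jy, jx = rng.uniform(-r / 2, r / 2, 2)
            rr, cc = draw.disk((cy + jy, cx + jx), r, shape=(h, w))
            mask[rr, cc] = True
    return mask


def render_scene(table: pd.DataFrame, config: SceneConfig) -> Scene:
    """Rasterize a nucleus table into ground truth + both modalities.

    Ground truth and fluorescence are drawn at the tabulated centers;
    the brightfield render is displaced by -modality_shift_px, so the
    ground-truth centroid minus the brightfield-footprint centroid equals
    the configured shift.  Later nuclei overwrite earlier ones in the
    ground truth (labels stay distinct); fully occluded nuclei are
    dropped from the realized table.
    """
    h, w = config.height, config.width
    rng = np.random.default_rng(config.seed + 1)
    dy, dx = config.modality_shift_px

    gt = np.zeros((h, w), dtype=np.int32)
    fluor = np.full((h, w), 0.05, dtype=np.float64)
    bf_dev = np.zeros((h, w), dtype=np.float64)       # in-focus deviation
    bf_dev_oof = np.zeros((h, w), dtype=np.float64)   # out-of-focus deviation

    rim_depth = 0.5 * config.contrast
    interior_lift = 0.2 * config.contrast
    body_amp = config.cell_body_amp * config.contrast
    # additive cell-body clutter, one canvas per focus state
    cyto_dev = np.zeros((h, w), dtype=np.float64)
    cyto_dev_oof = np.zeros((h, w), dtype=np.float64)
    for i, row in enumerate(table.itertuples(index=False)):
        label = i + 1
        rr, cc = _ellipse_pixels(row.cy, row.cx, row.r_major, row.r_minor,
                                 row.angle, (h, w))
        gt[rr, cc] = label
        fluor[rr, cc] = np.maximum(fluor[rr, cc], rng.uniform(0.7, 1.0))

        target = bf_dev if row.in_focus else bf_dev_oof
        bcy, bcx = row.cy - dy, row.cx - dx
        if config.cell_body_factor > 1 and body_amp > 0:
            # the surrounding cell body: faint transmitted-light texture
            # that accumulates where cells crowd, but leaves the cell's
            # own nucleus untouched
            brr, bcc = _ellipse_pixels(bcy, bcx,
                                       row.r_major * config.cell_body_factor,
                                       row.r_minor * config.cell_body_factor,
                                       row.angle, (h, w))
            delta = rng.uniform(-body_amp, body_amp)
            mask = np.zeros((h, w), dtype=bool)
            mask[brr, bcc] = True
            nrr, ncc = _ellipse_pixels(bcy, bcx, row.r_major, row.r_minor,
                                       row.angle, (h, w))
            mask[nrr, ncc] = False
            (cyto_dev if row.in_focus else cyto_dev_oof)[mask] += delta
        rr, cc = _ellipse_pixels(bcy, bcx, row.r_major, row.r_minor,
                                 row.angle, (h, w))
        target[rr, cc] = -rim_depth
        if row.r_minor > 3:  # overwrite the interior, leaving a dark ring
            irr, icc = _ellipse_pixels(bcy, bcx, row.r_major - 2,
                                       row.r_minor - 2, row.angle, (h, w))
            target[irr, icc] = interior_lift
    bf_dev = bf_dev + cyto_dev
    bf_dev_oof = bf_dev_oof + cyto_dev_oof

    fluor = ndimage.gaussian_filter(fluor, 1.0)
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0, config.noise_sd, (h, w))
    fluor = np.clip(fluor, 0, 1).astype(np.float32)

    bf_dev_oof = ndimage.gaussian_filter(bf_dev_oof, 4.0)

    focus = config.focus_plane
    if focus is None:
        focus = config.n_planes // 2
    planes = []
    for p in range(config.n_planes):
        sigma = abs(p - focus) * config.plane_blur_step
        dev = ndimage.gaussian_filter(bf_dev, sigma) if sigma > 0 else bf_dev
        plane = 0.5 + dev + bf_dev_oof
        if config.noise_sd > 0:
            plane = plane + rng.normal(0, config.noise_sd, (h, w))
        planes.append(np.clip(plane, 0, 1))
    bf = np.stack(planes, axis=-1).astype(np.float32)

    artifact_mask = np.zeros((h, w), dtype=bool)
    if config.artifact is not None:
        artifact_mask = _artifact_blobs(config, rng)
        opacity = config.artifact[2]
        dark = 0.05
        bf = (bf * np.where(artifact_mask, 1 - opacity, 1.0)[..., None]
              + (opacity * dark) * artifact_mask[..., None]).astype(np.float32)

    # drop fully occluded nuclei, keep labels contiguous in table order
    surviving = np.unique(gt)
    surviving = surviving[surviving > 0]
    table = table.reset_index(drop=True)
    keep = table.index[np.isin(table.index.to_numpy() + 1, surviving)]
    relabel = np.zeros(int(gt.max()) + 1, dtype=np.int32)
    for new, old in enumerate(np.asarray(keep) + 1, start=1):
        relabel[old] = new
    gt = relabel[gt]
    realized = table.loc[keep].reset_index(drop=True)
    realized.insert(0, "label", np.arange(1, len(realized) + 1))

    return Scene(gt=gt, fluorescence=fluor, brightfield=bf,
                 artifact_mask=artifact_mask, nuclei=realized, config=config)


def make_scene(config: SceneConfig) -> Scene:
    return render_scene(sample_nuclei(config), config)


# ---------------------------------------------------------------------------
# benchmark suites
# ---------------------------------------------------------------------------

def _image_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0]
               % (2 ** 31))


def preset_config(preset: str, index: int = 0, seed: int = 0,
                  **overrides) -> SceneConfig:
    """SceneConfig for image ``index`` of a named benchmark preset.

    Preset nucleus counts are densities for the preset's native field
    size; overriding ``height``/``width`` without an explicit
    ``n_nuclei`` rescales the count by the area ratio.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(_image_seed(seed, index))
    kw: dict = {}
    if preset == "seven_line_like":
        kw = {"n_nuclei": int(rng.poisson(353))}
    elif preset == "lncap_like":
        kw = {"height": 2156, "width": 2556, "n_nuclei": int(rng.poisson(681)),
              "radius_mean_px": 20.0, "radius_sd_px": 5.0}
    elif preset == "density_sweep":
        grid = overrides.pop("density_grid", DENSITY_GRID)
        kw = {"n_nuclei": int(grid[index % len(grid)])}
    elif preset == "size_sweep":
        grid = overrides.pop("size_grid", SIZE_GRID)
        kw = {"radius_mean_px": float(grid[index % len(grid)])}
    elif preset == "focal_stack":
        kw = {"n_nuclei": int(rng.poisson(353)), "n_planes": 9}
    native_area = kw.get("height", 1080) * kw.get("width", 1080)
    kw.update(overrides)
    if ("n_nuclei" not in overrides
            and ("height" in overrides or "width" in overrides)):
        area = kw.get("height", 1080) * kw.get("width", 1080)
        kw["n_nuclei"] = max(1, round(kw.get("n_nuclei", 353)
                                      * area / native_area))
    kw["seed"] = _image_seed(seed, index + 10_000)
    return SceneConfig(**kw)


def make_benchmark_suite(preset: str, n_images: int, out_dir, seed: int = 0,
                         **overrides) -> pd.DataFrame:
    """Write a suite of scenes + manifest to disk; returns the manifest.

    Emits ``images/*.tif`` (float32 brightfield stacks), ``masks/*.tif``
    (uint16 label maps), ``fluorescence/*.tif``, ``artifacts/*.tif`` when
    present, ``manifest.csv`` and ``meta.json``.  Scene configs follow the
    preset; ``overrides`` adjust any SceneConfig field (e.g. smaller
    fields for desk-scale runs).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = os.fspath(out_dir)
    for sub in ("images", "masks", "fluorescence"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    records, meta = [], []
    for i in range(n_images):
        cfg = preset_config(preset, i, seed, **dict(overrides))
        scene = make_scene(cfg)
        img_rel = f"images/img_{i:03d}.tif"
        mask_rel = f"masks/mask_{i:03d}.tif"
        imaging_io.write_image(os.path.join(out_dir, img_rel),
                               scene.brightfield)
        imaging_io.write_image(os.path.join(out_dir, mask_rel),
                               scene.gt.astype(np.uint16))
        imaging_io.write_image(
            os.path.join(out_dir, f"fluorescence/fluo_{i:03d}.tif"),
            scene.fluorescence)
        if scene.artifact_mask.any():
            os.makedirs(os.path.join(out_dir, "artifacts"), exist_ok=True)
            imaging_io.write_image(
                os.path.join(out_dir, f"artifacts/artifact_{i:03d}.tif"),
                scene.artifact_mask.astype(np.uint8))
        records.append({"image": img_rel, "mask": mask_rel,
                        "cell_line": preset, "well": f"W{i // 9:02d}",
                        "field": str(i % 9), "split": "train"})
        meta.append({"index": i, "n_nuclei_realized": int(len(scene.nuclei)),
                     **dataclasses.asdict(cfg)})
    if n_images >= 6:
        manifest = imaging_io.split_manifest(records, seed=seed)
    else:  # too few images to partition; callers re-split as needed
        manifest = imaging_io.split_manifest(records,
                                             counts=(n_images, 0, 0), seed=seed)
    imaging_io.write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=list)
    return manifest
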