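"""Experiment runners: benchmark comparison, training-set-size ablation,
transfer/fine-tuning, and the focal-plane selection study.

Every runner is a pure function of (data, plan, seed) and emits tidy
pandas DataFrames.  Data can be given either as an in-memory mapping
``{"train": [(image, mask), ...], "val": [...], "test": [...]}`` or as a
dataset manifest (DataFrame) plus a root directory, in which case images
and masks are loaded and robust-normalized from disk.

Desk-scale defaults keep runs CPU-feasible: width-reduced networks
(base_filters 16) and 96 x 96 patches; ``full=True`` switches a plan to
the full-width 288-input configuration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import imaging_io
from .architectures import (DEFAULT_BATCH_SIZE, DEFAULT_LEARNING_RATE,
                            DEFAULT_SMOOTHING, ArchitectureSpec, build)
from .evaluation import object_report, pixel_metrics
from .postprocessing import postprocess
from .training import TrainConfig, expand_dataset, train

SIZE_GRID_ALL = (1, 2, 4, 8, 16, 32, 64, 128, 286)
FINE_TUNE_ALL = (1, 2, 4, 8, 16, 32, 64, 128)

EXPERIMENT_KINDS = ("benchmark", "data_ablation", "transfer", "focal_planes",
                    "arch_ablation")


def _derive_seed(seed: int, *keys) -> int:
    parts = [seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentPlan:
    """Declarative description of one experiment design."""

    kind: str
    archs: list = field(default_factory=lambda: [ArchitectureSpec("ppunet")])
    size_grid: tuple = (1, 2, 4, 8, 16, 32, 64, 286)
    regimes: tuple = ("plain", "smoothing", "augmentation")
    fine_tune_counts: tuple = (0, 1, 2, 4, 8, 16, 32, 64, 128)
    transfer_modes: tuple = ("target_only", "both")
    candidate_planes: tuple | None = None  # default: all 9
    max_planes: int | None = None
    smoothing_factors: dict = field(default_factory=lambda: dict(DEFAULT_SMOOTHING))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        patch_size=96, max_epochs=3, steps_per_epoch=50))
    full: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if not set(self.size_grid) <= set(SIZE_GRID_ALL):
            raise ValueError(f"size_grid must be a subset of {SIZE_GRID_ALL}")
        if not set(self.fine_tune_counts) <= set((0,) + FINE_TUNE_ALL):
            raise ValueError(
                f"fine_tune_counts must be a subset of {FINE_TUNE_ALL}")

    def arch_spec(self, spec: ArchitectureSpec) -> ArchitectureSpec:
        """Desk-scale (width-reduced) or full-scale version of a spec."""
        if self.full:
            return spec
        reduced = {"unet": 16, "ppunet": 16, "unetpp": 8, "tiramisu": 8}
        return replace(spec, base_filters=spec.base_filters
                       or reduced[spec.family],
                       input_size=min(spec.input_size, 96))

    def train_config(self, family: str, regime: str = "plain",
                     seed_key: tuple = ()) -> TrainConfig:
        cfg = self.train
        return cfg.scaled(
            smoothing=self.smoothing_factors.get(family, 0.15)
            if regime == "smoothing" else 0.0,
            augment=regime == "augmentation",
            learning_rate=cfg.learning_rate or DEFAULT_LEARNING_RATE[family],
            batch_size=cfg.batch_size or DEFAULT_BATCH_SIZE[family],
            seed=_derive_seed(self.seed, family, regime, *seed_key))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def load_pairs(manifest: pd.DataFrame, root, split: str):
    """Load (image, mask) arrays for one manifest split."""
    import os
    rows = manifest[manifest["split"] == split]
    pairs = []
    for _, row in rows.iterrows():
        img = imaging_io.read_image(os.path.join(root, row["image"]),
                                    normalize=True).pixels
        msk = imaging_io.read_image(os.path.join(root, row["mask"])).pixels
        pairs.append((img, (msk[..., 0] > 0).astype(np.float32)))
    return pairs


def resolve_data(data, root=None) -> dict:
    if isinstance(data, dict):
        return data
    manifest = data
    return {split: load_pairs(manifest, root or ".", split)
            for split in ("train", "val", "test")}


def evaluate_pixel_f1(net, pairs, patch_size: int | None = None) -> float:
    """Mean full-field pixel F1 (0.5 cutoff) over (image, mask) pairs."""
    scores = []
    for img, msk in pairs:
        prob = imaging_io.predict_full_field(net, img, patch_size)
        scores.append(pixel_metrics(prob >= 0.5, msk > 0).f1)
    return float(np.mean(scores))


def _fit(plan: ExperimentPlan, spec: ArchitectureSpec, train_pairs, val_pairs,
         regime: str = "plain", seed_key: tuple = (), init_weights=None):
    spec = plan.arch_spec(spec)
    cfg = plan.train_config(spec.family, regime, seed_key)
    net = build(spec, seed=_derive_seed(plan.seed, "init", spec.family, *seed_key))
    if init_weights is not None:
        net.set_weights(init_weights)
    stream = expand_dataset(train_pairs, do_augment=cfg.augment, seed=cfg.seed)
    net, history = train(net, stream, val_pairs, cfg)
    return net, history


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def run_data_ablation(plan: ExperimentPlan, data, root=None) -> pd.DataFrame:
    """Pixel F1 per (architecture, training-set size, regime).

    Subsets are nested (the n=4 set contains the n=2 set) to control
    sampling variance across sizes.
    """
    d = resolve_data(data, root)
    train_pairs, val_pairs, test_pairs = d["train"], d["val"], d["test"]
    need = max(plan.size_grid)
    if len(train_pairs) < need:
        raise ValueError(f"need {need} training images, have {len(train_pairs)}")
    order = np.random.default_rng(_derive_seed(plan.seed, "subset")).permutation(
        len(train_pairs))
    rows = []
    for spec in plan.archs:
        for n in sorted(plan.size_grid):
            subset = [train_pairs[i] for i in order[:n]]
            for regime in plan.regimes:
                net, _ = _fit(plan, spec, subset, val_pairs, regime,
                              seed_key=(n,))
                f1 = evaluate_pixel_f1(net, test_pairs,
                                       plan.train.patch_size)
                rows.append({"family": spec.family, "n_images": n,
                             "regime": regime, "pixel_f1": f1})
    return pd.DataFrame(rows)


def _interleave(a, b):
    out = []
    for x, y in zip(a, b):
        out.extend([x, y])
    return out


def run_transfer(plan: ExperimentPlan, source_data, target_data,
                 root=None) -> pd.DataFrame:
    """Fine-tuning across domains.

    A source model is trained once, then fine-tuned with ``n`` target
    images (mode ``target_only``) or ``n`` target + ``n`` source images
    interleaved (mode ``both``); each fine-tuned model is evaluated on
    both domains' test splits.  ``n = 0`` rows measure pure domain shift.
    """
    src = resolve_data(source_data, root)
    tgt = resolve_data(target_data, root)
    spec = plan.archs[0]
    source_net, _ = _fit(plan, spec, src["train"], src["val"],
                         seed_key=("source",))
    base_weights = source_net.get_weights()
    rows = []
    for n in plan.fine_tune_counts:
        for mode in plan.transfer_modes:
            if n == 0:
                net = source_net
            else:
                if n > len(tgt["train"]):
                    raise ValueError(f"need {n} target images, have "
                                     f"{len(tgt['train'])}")
                ft_pairs = list(tgt["train"][:n])
                if mode == "both":
                    ft_pairs = _interleave(src["train"][:n], ft_pairs)
                net, _ = _fit(plan, spec, ft_pairs, tgt["val"],
                              seed_key=("ft", n, mode),
                              init_weights=base_weights)
            rows.append({
                "n_finetune": n, "mode": mode,
                "f1_source": evaluate_pixel_f1(net, src["test"],
                                               plan.train.patch_size),
                "f1_target": evaluate_pixel_f1(net, tgt["test"],
                                               plan.train.patch_size)})
    return pd.DataFrame(rows)


def replicate_planes(stack: np.ndarray, planes: list[int],
                     n_channels: int = 9) -> np.ndarray:
    """Fill ``n_channels`` input channels from the chosen focal planes.

    With k unique planes each is repeated ceil(9/k) or floor(9/k) times;
    earlier-picked planes receive the extra copies.
    """
    k = len(planes)
    if k < 1:
        raise ValueError("need at least one plane")
    base, rem = divmod(n_channels, k)
    counts = [base + (1 if i < rem else 0) for i in range(k)]
    chans = []
    for p, c in zip(planes, counts):
        chans.extend([stack[..., p]] * c)
    return np.stack(chans, axis=-1)


def run_focal_planes(plan: ExperimentPlan, data, root=None,
                     score_fn=None):
    """Greedy forward selection of focal planes.

    Round 1 trains one model per candidate plane (the plane replicated to
    all 9 input channels) and keeps the best by validation F1; each later
    round adds the best remaining plane.  Returns (results DataFrame,
    picked plane order).  ``score_fn(train_pairs, val_pairs, test_pairs,
    planes)`` may replace the training step (used for fast protocol
    tests); it returns (val_f1, test_f1).
    """
    d = resolve_data(data, root)
    for img, _ in d["train"]:
        if img.shape[-1] != 9:
            raise ValueError(f"focal-plane study needs 9-plane stacks, "
                             f"got C={img.shape[-1]}")
    candidates = list(plan.candidate_planes
                      if plan.candidate_planes is not None else range(9))
    max_planes = plan.max_planes or len(candidates)
    spec = replace(plan.archs[0], in_channels=9)

    def default_score(train_pairs, val_pairs, test_pairs, planes):
        sub = lambda pairs: [(replicate_planes(img, planes), msk)
                             for img, msk in pairs]
        net, _ = _fit(plan, spec, sub(train_pairs), sub(val_pairs),
                      seed_key=("planes",) + tuple(planes))
        return (evaluate_pixel_f1(net, sub(val_pairs), plan.train.patch_size),
                evaluate_pixel_f1(net, sub(test_pairs), plan.train.patch_size))

    score = score_fn or default_score
    chosen: list[int] = []
    rows = []
    while len(chosen) < max_planes:
        results = []
        for p in sorted(set(candidates) - set(chosen)):
            val_f1, test_f1 = score(d["train"], d["val"], d["test"],
                                    chosen + [p])
            results.append((val_f1, p, test_f1))
        best_val, best_plane, best_test = max(
            results, key=lambda t: (t[0], -t[1]))  # tie -> lowest plane
        chosen.append(best_plane)
        rows.append({"n_planes": len(chosen), "picked_plane": best_plane,
                     "val_f1": best_val, "test_f1": best_test})
    return pd.DataFrame(rows), chosen


def run_benchmark(plan: ExperimentPlan, data, root=None):
    """Train each architecture; full pixel + object evaluation per image.

    Returns (summary DataFrame, per-image DataFrame).
    """
    d = resolve_data(data, root)
    per_image = []
    summaries = []
    for spec in plan.archs:
        net, _ = _fit(plan, spec, d["train"], d["val"],
                      seed_key=("benchmark",))
        for i, (img, msk) in enumerate(d["test"]):
            prob = imaging_io.predict_full_field(net, img,
                                                 plan.train.patch_size)
            labels = postprocess(prob)
            gt_labels = postprocess((msk > 0).astype(float))
            pm = pixel_metrics(labels > 0, msk > 0)
            orep = object_report(gt_labels, labels)
            per_image.append({
                "family": spec.family, "image_index": i,
                "n_objects_gt": int(gt_labels.max()),
                "pixel_f1": pm.f1, "balanced_accuracy": pm.balanced_accuracy,
                "object_f1_avg": orep.f1_avg, "merges": orep.merges,
                "splits": orep.splits, "missed": orep.missed})
        df = pd.DataFrame([r for r in per_image if r["family"] == spec.family])
        summaries.append({
            "family": spec.family,
            "pixel_f1": df["pixel_f1"].mean(),
            "balanced_accuracy": df["balanced_accuracy"].mean(),
            "object_f1_avg": df["object_f1_avg"].mean(),
            "merges": df["merges"].sum(), "splits": df["splits"].sum(),
            "missed": df["missed"].sum()})
    return pd.DataFrame(summaries), pd.DataFrame(per_image)
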