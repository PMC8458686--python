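"""Training strategies: label smoothing, orientation augmentation, the
learning-rate range test, and the plateau/early-stop training loop.

All networks are trained with Adam on binary cross-entropy against
(optionally smoothed) nucleus masks.  The schedule follows the protocol
used throughout the experiments: up to ``max_epochs`` epochs of
``10000 / batch_size`` optimizer steps, the learning rate divided by 10
after 10 consecutive epochs without validation-loss improvement, and a
full stop after 20; the weights with the best validation loss are
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn

AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")


# ---------------------------------------------------------------------------
# targets and loss
# ---------------------------------------------------------------------------

def smooth_labels(mask: np.ndarray, s: float) -> np.ndarray:
    """Soften hard 0/1 targets to s/(1-s) to acknowledge annotation noise."""
    if not 0 <= s < 0.5:
        raise ValueError(f"smoothing factor {s} outside [0, 0.5)")
    mask = np.asarray(mask, dtype=np.float32)
    return mask * (1.0 - 2.0 * s) + s


def bce_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of probabilities against (soft) targets."""
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(t * np.log(p) + (1 - t) * np.log1p(-p)).mean())


# ---------------------------------------------------------------------------
# augmentation (the dihedral orbit of flips and right-angle rotations)
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, op: str):
    """Apply one lossless orientation transform jointly to image and mask.

    ``rot90`` is counterclockwise in (row, col) axes, matching
    ``np.rot90``; flips are along the stated image axis.  Works for 2-D
    arrays and H x W x C stacks (the transform acts on the spatial axes).
    """
    image, mask = np.asarray(image), np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask spatial shapes differ")

    def tf(a):
        if op == "hflip":
            return a[:, ::-1].copy()
        if op == "vflip":
            return a[::-1].copy()
        if op == "rot90":
            return np.rot90(a, 1, axes=(0, 1)).copy()
        if op == "rot180":
            return np.rot90(a, 2, axes=(0, 1)).copy()
        if op == "rot270":
            return np.rot90(a, 3, axes=(0, 1)).copy()
        raise ValueError(f"unknown augmentation op {op!r}")

    return tf(image), tf(mask)


def oriented_epoch(pairs, do_augment: bool, rng) -> list:
    """One epoch's worth of oriented pairs: identity (+ 5 ops), shuffled."""
    out = []
    for img, msk in pairs:
        out.append((img, msk))
        if do_augment:
            for op in AUGMENT_OPS:
                out.append(augment(img, msk, op))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def expand_dataset(pairs, do_augment: bool = True, seed: int = 0):
    """Infinite deterministic stream of (image, mask) training pairs.

    With augmentation every source pair contributes 6 distinct oriented
    pairs per epoch; order is reshuffled each epoch from ``seed``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    rng = np.random.default_rng(seed)
    while True:
        yield from oriented_epoch(pairs, do_augment, rng)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def random_crop(img: np.ndarray, msk: np.ndarray, size: int, rng):
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop {size}")
    r = int(rng.integers(0, h - size + 1))
    c = int(rng.integers(0, w - size + 1))
    return img[r:r + size, c:c + size], msk[r:r + size, c:c + size]


def _to_nchw(images):
    arrs = []
    for a in images:
        a = np.asarray(a, dtype=np.float32)
        if a.ndim == 2:
            a = a[..., None]
        arrs.append(a.transpose(2, 0, 1))
    return np.stack(arrs)


def make_batch(stream, batch_size: int, patch: int, rng, smoothing: float = 0.0):
    """Draw the next ``batch_size`` pairs, random-crop, stack, smooth."""
    xs, ts = [], []
    for _ in range(batch_size):
        img, msk = next(stream)
        if min(img.shape[:2]) > patch:
            img, msk = random_crop(img, msk, patch, rng)
        xs.append(img)
        ts.append((np.asarray(msk) > 0).astype(np.float32))
    x = _to_nchw(xs)
    t = np.stack(ts)[:, None]
    return x, smooth_labels(t, smoothing)


# ---------------------------------------------------------------------------
# learning-rate range test
# ---------------------------------------------------------------------------

@dataclass
class LRCurve:
    """Loss response over a geometric learning-rate grid."""

    rates: np.ndarray
    losses: np.ndarray
    candidate: float

    smoothed: np.ndarray = field(default=None, repr=False)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if len(x) < window:
        return x.copy()
    kernel = np.ones(window) / window
    sm = np.convolve(x, kernel, mode="valid")
    # pad edges with the nearest smoothed value to keep the grid aligned
    lead = window // 2
    return np.concatenate([np.full(lead, sm[0]), sm,
                           np.full(len(x) - len(sm) - lead, sm[-1])])


def lr_range_test(net, stream, n_steps: int = 100, batch_size: int = 4,
                  patch: int = 96, seed: int = 0,
                  lr_min: float = 1e-10, lr_max: float = 10.0,
                  smoothing_window: int = 5) -> LRCurve:
    """Sweep a geometric learning-rate grid, one optimizer step per rate.

    The candidate rate is the one giving the largest drop of the
    (moving-average smoothed) loss; a NaN loss truncates the sweep and the
    candidate is computed on the prefix.  Ties break to the smallest rate.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    rng = np.random.default_rng(seed)
    rates = np.geomspace(lr_min, lr_max, n_steps)
    opt = nn.Adam(net.parameters(), lr=rates[0])
    net.set_training(True)
    losses = []
    for rate in rates:
        x, t = make_batch(stream, batch_size, patch, rng)
        loss = nn.bce_with_logits(net.forward_logits(x), t)
        if not np.isfinite(loss.data):
            break
        losses.append(float(loss.data))
        opt.zero_grad()
        nn.backward(loss)
        opt.lr = float(rate)
        opt.step()
    losses = np.array(losses)
    used = rates[:len(losses)]
    sm = _moving_average(losses, smoothing_window)
    if len(sm) < 2:
        candidate = float(used[0])
    else:
        drops = -np.diff(sm)  # positive where the loss falls
        best = int(np.argmax(drops))  # argmax takes the first (smallest rate) tie
        candidate = float(used[best])
    return LRCurve(rates=used, losses=losses, candidate=candidate, smoothed=sm)


# ---------------------------------------------------------------------------
# plateau schedule and the training loop
# ---------------------------------------------------------------------------

class PlateauScheduler:
    """Reduce-on-plateau with early stop, as a pure function of val losses.

    Improvement means the new validation loss undercuts the best seen by
    more than ``tol``.  After ``patience_reduce`` consecutive
    non-improving epochs the learning rate is divided by ``factor``; after
    ``patience_stop`` training stops.
    """

    def __init__(self, patience_reduce: int = 10, patience_stop: int = 20,
                 factor: float = 10.0, tol: float = 1e-6):
        if patience_reduce >= patience_stop:
            raise ValueError("plateau patience must be below stop patience")
        self.patience_reduce = patience_reduce
        self.patience_stop = patience_stop
        self.factor = factor
        self.tol = tol
        self.best = np.inf
        self.streak = 0

    def update(self, val_loss: float) -> dict:
        """Feed one epoch's validation loss; returns the actions due."""
        improved = val_loss < self.best - self.tol
        if improved:
            self.best = val_loss
            self.streak = 0
        else:
            self.streak += 1
        stop = self.streak >= self.patience_stop
        reduce = (not stop and self.streak > 0
                  and self.streak % self.patience_reduce == 0)
        return {"improved": improved, "reduce": reduce, "stop": stop}


def simulate_schedule(val_losses, patience_reduce=10, patience_stop=20,
                      factor=10.0, lr0=1.0, tol=1e-6):
    """Reference trace of the plateau schedule over a val-loss sequence.

    Returns (per-epoch lr list, stop_epoch or None), 1-based epochs.
    """
    sched = PlateauScheduler(patience_reduce, patience_stop, factor, tol)
    lr = lr0
    lrs, stop_epoch = [], None
    for epoch, v in enumerate(val_losses, start=1):
        act = sched.update(v)
        if act["reduce"]:
            lr /= factor
        lrs.append(lr)
        if act["stop"]:
            stop_epoch = epoch
            break
    return lrs, stop_epoch


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    learning_rate: float = 5e-4
    batch_size: int = 8
    smoothing: float = 0.0
    augment: bool = False
    max_epochs: int = 500
    steps_per_epoch: int | None = None  # defaults to 10000 // batch_size
    plateau_patience: int = 10
    stop_patience: int = 20
    lr_decay_factor: float = 10.0
    patch_size: int = 288
    val_batches: int = 4
    seed: int = 0

    def __post_init__(self):
        # coerce YAML-friendly strings ("1e-3") and ints
        self.learning_rate = float(self.learning_rate)
        self.smoothing = float(self.smoothing)
        self.lr_decay_factor = float(self.lr_decay_factor)
        for name in ("batch_size", "max_epochs", "plateau_patience",
                     "stop_patience", "patch_size", "val_batches", "seed"):
            setattr(self, name, int(getattr(self, name)))
        if self.steps_per_epoch is not None:
            self.steps_per_epoch = int(self.steps_per_epoch)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.plateau_patience >= self.stop_patience:
            raise ValueError("plateau patience must be below stop patience")
        if self.steps_per_epoch is None:
            self.steps_per_epoch = max(1, 10000 // self.batch_size)

    def scaled(self, **overrides) -> "TrainConfig":
        return replace(self, **overrides)


def train(net, train_stream, val_pairs, config: TrainConfig):
    """Plateau-scheduled Adam training; returns (net, history DataFrame).

    ``train_stream`` is an (infinite) iterator of (image, mask) pairs, as
    produced by :func:`expand_dataset`.  Validation loss is computed on a
    fixed set of patches cropped once from ``val_pairs`` with the config
    seed, which keeps the schedule deterministic.  The network is left
    with (a copy of) the best-validation weights.
    """
    rng = np.random.default_rng(config.seed)
    val_list = list(val_pairs)
    if not val_list:
        raise ValueError("empty validation set")
    vx, vt = [], []
    n_val = min(config.val_batches, len(val_list)) or len(val_list)
    vrng = np.random.default_rng(config.seed + 1)
    for img, msk in (val_list * ((n_val // len(val_list)) + 1))[:n_val]:
        if min(np.asarray(img).shape[:2]) > config.patch_size:
            img, msk = random_crop(img, msk, config.patch_size, vrng)
        vx.append(img)
        vt.append((np.asarray(msk) > 0).astype(np.float32))
    vx = _to_nchw(vx)
    vt = np.stack(vt)[:, None]
    vt_s = smooth_labels(vt, config.smoothing)

    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    sched = PlateauScheduler(config.plateau_patience, config.stop_patience,
                             config.lr_decay_factor)
    best_weights = net.get_weights()
    history = []
    for epoch in range(1, config.max_epochs + 1):
        net.set_training(True)
        train_losses = []
        for _ in range(config.steps_per_epoch):
            x, t = make_batch(train_stream, config.batch_size,
                              config.patch_size, rng, config.smoothing)
            loss = nn.bce_with_logits(net.forward_logits(x), t)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {epoch}")
            train_losses.append(float(loss.data))
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
        net.set_training(False)
        val_logits = net.forward_logits(vx)
        val_loss = float(nn.bce_with_logits(val_logits, vt_s).data)
        act = sched.update(val_loss)
        if act["improved"]:
            best_weights = net.get_weights()
        if act["reduce"]:
            opt.lr /= config.lr_decay_factor
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": val_loss, "lr": opt.lr})
        if act["stop"]:
            break
    net.set_weights(best_weights)
    return net, pd.DataFrame(history)
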