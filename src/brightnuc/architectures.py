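"""Encoder-decoder segmentation networks for brightfield nucleus detection.

Four families are provided, all end-to-end encoder-decoder networks mapping
a grayscale patch to a per-pixel nucleus probability map:

``unet``
    The baseline: five resolution levels of three 3x3/64-filter
    convolutions per path, a three-convolution bottleneck, concatenation
    skips, parameter-free bilinear upsampling (~1.37 M parameters).
``unetpp``
    Nested dense skip pathways between a four-level backbone
    (32/64/128/256 filters, 512-filter bottleneck) with batch
    normalization and transposed-convolution upsampling (~9.0 M).
``tiramisu``
    Fully convolutional DenseNet: dense blocks of (4,5,7,10,12) layers
    down, 15-layer bottleneck, (12,10,7,5,4) up, growth rate 16, 48-filter
    stem (~9.3 M).
``ppunet``
    Pyramid-pooling U-Net: ten two-convolution residual blocks per path
    plus a two-block bottleneck (64 filters throughout), with every long
    skip routed through a five-level average-pooling pyramid whose levels
    are reprojected by sixteen 1x1 convolutions (~2.1 M).  The lightest of
    the well-performing family.

Architecture variants used in the ablation study (doubled skip taps,
batch normalization, a filter pyramid for the baseline, halved skip-path
blocks for unetpp) are selected through ``ArchitectureSpec.variant_flags``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

VALID_FLAGS = {"double_skips", "batch_norm", "filter_pyramid", "half_skip_convs"}
FAMILIES = ("unet", "unetpp", "tiramisu", "ppunet")

#: batch sizes used when training each family (processing-budget defaults;
#: the deeplab slot of the published quintet is out of scope here)
DEFAULT_BATCH_SIZE = {"unet": 16, "unetpp": 8, "tiramisu": 4, "ppunet": 8}

#: learning rates selected by the range test for brightfield inputs
DEFAULT_LEARNING_RATE = {"unet": 1e-5, "unetpp": 1e-3, "tiramisu": 5e-4,
                         "ppunet": 5e-4}

#: label-smoothing factors selected by grid search per family
DEFAULT_SMOOTHING = {"unet": 0.05, "unetpp": 0.15, "tiramisu": 0.20,
                     "ppunet": 0.15}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a buildable network.

    ``base_filters`` means the convolution width for ``unet``/``ppunet``
    (default 64), the first-level width for ``unetpp`` (default 32, deeper
    levels double), and the dense-block growth rate for ``tiramisu``
    (default 16, stem = 3x growth).  Reduced values give the width-reduced
    desk-scale variants used in the experiment runners.
    """

    family: str
    in_channels: int = 1
    input_size: int = 288
    base_filters: int | None = None
    variant_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 1 <= self.in_channels <= 9:
            raise ValueError("in_channels must be in [1, 9]")
        bad = set(self.variant_flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown variant flags {sorted(bad)}")
        div = divisibility(self.family)
        if self.input_size % div:
            raise ValueError(
                f"input_size {self.input_size} not divisible by {div} "
                f"(required for {self.family})")

    def to_dict(self):
        return {"family": self.family, "in_channels": self.in_channels,
                "input_size": self.input_size, "base_filters": self.base_filters,
                "variant_flags": sorted(self.variant_flags)}

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["variant_flags"] = frozenset(d.get("variant_flags") or ())
        return cls(**d)


def divisibility(family: str) -> int:
    """Spatial-size divisor each family requires (2^number of poolings)."""
    return 16 if family == "unetpp" else 32


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------

class ConvBlock(nn.Module):
    """conv3x3 -> (BN) -> ReLU, repeated ``n`` times."""

    def __init__(self, cin, cout, n, rng, batch_norm=False):
        super().__init__()
        self.convs = nn.ModuleList()
        self.bns = nn.ModuleList() if batch_norm else None
        c = cin
        for _ in range(n):
            self.convs.append(nn.Conv2d(c, cout, 3, rng))
            if batch_norm:
                self.bns.append(nn.BatchNorm2d(cout))
            c = cout

    def __call__(self, x):
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if self.bns is not None:
                x = self.bns[i](x)
            x = nn.relu(x)
        return x


class PyramidPooling(nn.Module):
    """Five-level average-pooling pyramid with 1x1 reprojection.

    Pool sizes 16/8/4/2/1 with stride equal to the pool size; each pooled
    map passes through ``proj`` 1x1 convolutions, batch normalization and
    ReLU, is resized bilinearly back to the input resolution, and is
    concatenated with the input.  Output channels = in + 5 * proj.
    Pool sizes larger than the feature map are clipped, and border windows
    are edge-clipped, so the +5*proj channel contract holds at any
    resolution.
    """

    POOLS = (16, 8, 4, 2, 1)

    def __init__(self, cin, rng, proj=16):
        super().__init__()
        self.proj = proj
        self.convs = nn.ModuleList([nn.Conv2d(cin, proj, 1, rng)
                                    for _ in self.POOLS])
        self.bns = nn.ModuleList([nn.BatchNorm2d(proj) for _ in self.POOLS])

    def __call__(self, x):
        h, w = x.data.shape[2:]
        outs = [x]
        for pool, conv, bn in zip(self.POOLS, self.convs, self.bns):
            y = nn.avgpool2d(x, pool)
            y = nn.relu(bn(conv(y)))
            outs.append(nn.bilinear_resize(y, (h, w)))
        return nn.concat(outs, axis=1)


def pyramid_pooling_block(features: np.ndarray, proj: int = 16,
                          seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized pyramid pooling module to ``features``.

    ``features`` is H x W x C; the result is H x W x (C + 5 * proj).
    Convenience wrapper for inspecting the module in isolation; networks
    embed :class:`PyramidPooling` directly.
    """
    arr = np.asarray(features, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected an H x W x C feature array")
    mod = PyramidPooling(arr.shape[2], np.random.default_rng(seed))
    mod.set_training(False)
    x = nn.Node(arr.transpose(2, 0, 1)[None])
    out = mod(x)
    return out.data[0].transpose(1, 2, 0)


class Network(nn.Module):
    """Base class: trainable patch -> probability-map function."""

    family = ""

    def __init__(self, spec: ArchitectureSpec):
        super().__init__()
        self.spec = spec

    # subclasses implement forward() returning the logits node
    def forward(self, x: nn.Node) -> nn.Node:
        raise NotImplementedError

    def _check_input(self, x):
        h, w = x.shape[2:]
        div = divisibility(self.spec.family)
        if h % div or w % div:
            raise ValueError(
                f"{self.spec.family} input {h}x{w} not divisible by {div}")

    def forward_logits(self, x) -> nn.Node:
        x = nn.as_node(np.asarray(x, dtype=np.float32))
        self._check_input(x.data)
        return self.forward(x)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one H x W x C image (eval mode)."""
        was_training = self.training
        self.set_training(False)
        try:
            arr = np.asarray(image, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[..., None]
            x = arr.transpose(2, 0, 1)[None]
            probs = nn.sigmoid(self.forward_logits(x)).data[0, 0]
        finally:
            self.set_training(was_training)
        return probs

    @property
    def parameter_count(self) -> int:
        return count_trainable_parameters(self)

    @property
    def conv_layer_count(self) -> int:
        """Number of k>=3 convolution layers (terminal 1x1 head excluded)."""
        return sum(1 for m in self.modules()
                   if isinstance(m, nn.Conv2d) and m.k >= 3)


def count_trainable_parameters(net: nn.Module) -> int:
    """Sum of sizes of all trainable tensors (BN running stats excluded)."""
    return int(sum(p.data.size for p in net.parameters()))


# ---------------------------------------------------------------------------
# U-Net baseline and its ablation variants
# ---------------------------------------------------------------------------

class UNet(Network):
    """Baseline with 15 + 3 + 15 convolutions (skip/pool every third)."""

    family = "unet"
    LEVELS = 5

    def __init__(self, spec, rng):
        super().__init__(spec)
        w = spec.base_filters or 64
        flags = spec.variant_flags
        self.double_skips = "double_skips" in flags
        bn = "batch_norm" in flags
        if "filter_pyramid" in flags:
            widths = [min(w * 2 ** l, w * 8) for l in range(self.LEVELS)]
        else:
            widths = [w] * self.LEVELS
        self.widths = widths

        self.enc = nn.ModuleList()
        c = spec.in_channels
        for l in range(self.LEVELS):
            self.enc.append(ConvBlock(c, widths[l], 3, rng, bn))
            c = widths[l]
        self.bottleneck = ConvBlock(c, widths[-1], 3, rng, bn)
        self.dec = nn.ModuleList()
        c = widths[-1]
        for l in reversed(range(self.LEVELS)):
            skip = widths[l] * (2 if self.double_skips else 1)
            self.dec.append(ConvBlock(c + skip, widths[l], 3, rng, bn))
            c = widths[l]
        self.head = nn.Conv2d(c, 1, 1, rng)

    def forward(self, x):
        skips = []
        for block in self.enc:
            h = x
            for i, conv in enumerate(block.convs):
                h = conv(h)
                if block.bns is not None:
                    h = block.bns[i](h)
                h = nn.relu(h)
                if self.double_skips and i == 1:
                    second_tap = h
            taps = [h, second_tap] if self.double_skips else [h]
            skips.append(taps)
            x = nn.maxpool2d(h)
        x = self.bottleneck(x)
        for block, taps in zip(self.dec, reversed(skips)):
            up = nn.bilinear_resize(x, (x.data.shape[2] * 2, x.data.shape[3] * 2))
            x = block(nn.concat([up] + taps, axis=1))
        return self.head(x)


# ---------------------------------------------------------------------------
# U-Net++
# ---------------------------------------------------------------------------

class UNetPP(Network):
    """Nested-skip architecture over a 5-deep backbone.

    Grid nodes X(i, j): i indexes resolution (0 finest ... 4 bottleneck),
    j = 0 is the backbone, j >= 1 are the skip-pathway / expansion blocks.
    Node X(i, j) consumes the concatenation of all previous row-i nodes and
    a transposed-convolution upsampling of the newest available node one
    level below.  ``half_skip_convs`` halves (rounding up) the number of
    intermediate skip-pathway blocks per row.
    """

    family = "unetpp"

    def __init__(self, spec, rng):
        super().__init__(spec)
        b = spec.base_filters or 32
        widths = [b, b * 2, b * 4, b * 8, b * 16]
        self.widths = widths
        half = "half_skip_convs" in spec.variant_flags

        # nodes per row above the backbone: intermediates + final
        self.row_nodes = []
        for i in range(4):
            inter = 3 - i
            if half:
                inter = -(-inter // 2)  # ceil
            self.row_nodes.append(inter if i < 3 else 0)
        # row i has row_nodes[i] intermediates plus one expansion node
        self.backbone = nn.ModuleList()
        c = spec.in_channels
        for i in range(5):
            self.backbone.append(ConvBlock(c, widths[i], 2, rng, batch_norm=True))
            c = widths[i]
        self.ups = nn.ModuleList()   # per (row, j) transposed conv
        self.skip_blocks = nn.ModuleList()
        self._grid_index = {}
        for i in range(4):
            n_total = self.row_nodes[i] + 1
            for j in range(1, n_total + 1):
                self._grid_index[(i, j)] = len(self.skip_blocks)
                self.ups.append(nn.ConvTranspose2d(widths[i + 1], widths[i], 2, rng))
                cin = widths[i] * (j + 1)  # j previous row nodes + upsampled
                self.skip_blocks.append(ConvBlock(cin, widths[i], 2, rng, batch_norm=True))
        self.head = nn.Conv2d(widths[0], 1, 1, rng)

    def forward(self, x):
        rows = [None] * 5
        h = x
        for i in range(5):
            h = self.backbone[i](h)
            rows[i] = [h]
            if i < 4:
                h = nn.maxpool2d(h)
        for i in reversed(range(4)):
            n_total = self.row_nodes[i] + 1
            for j in range(1, n_total + 1):
                k = self._grid_index[(i, j)]
                donor = rows[i + 1][min(j - 1, len(rows[i + 1]) - 1)]
                up = self.ups[k](donor)
                node = self.skip_blocks[k](nn.concat(rows[i] + [up], axis=1))
                rows[i].append(node)
        return self.head(rows[0][-1])


# ---------------------------------------------------------------------------
# Tiramisu (fully convolutional DenseNet)
# ---------------------------------------------------------------------------

class DenseLayer(nn.Module):
    """BN -> ReLU -> conv3x3(growth)."""

    def __init__(self, cin, growth, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(cin)
        self.conv = nn.Conv2d(cin, growth, 3, rng)

    def __call__(self, x):
        return self.conv(nn.relu(self.bn(x)))


class DenseBlock(nn.Module):
    """``n`` dense layers; returns (full concatenation, new features)."""

    def __init__(self, cin, n, growth, rng):
        super().__init__()
        self.layers = nn.ModuleList()
        c = cin
        for _ in range(n):
            self.layers.append(DenseLayer(c, growth, rng))
            c += growth
        self.out_channels = c

    def __call__(self, x):
        feats = [x]
        news = []
        for layer in self.layers:
            y = layer(nn.concat(feats, axis=1) if len(feats) > 1 else feats[0])
            feats.append(y)
            news.append(y)
        return nn.concat(feats, axis=1), nn.concat(news, axis=1)


class TransitionDown(nn.Module):
    """BN -> ReLU -> conv1x1 -> 2x2 max pool."""

    def __init__(self, c, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(c)
        self.conv = nn.Conv2d(c, c, 1, rng)

    def __call__(self, x):
        return nn.maxpool2d(self.conv(nn.relu(self.bn(x))))


class Tiramisu(Network):
    family = "tiramisu"
    DOWN = (4, 5, 7, 10, 12)
    BOTTLENECK = 15
    UP = (12, 10, 7, 5, 4)

    def __init__(self, spec, rng):
        super().__init__(spec)
        g = spec.base_filters or 16
        self.stem = nn.Conv2d(spec.in_channels, 3 * g, 3, rng)
        c = 3 * g
        self.down_blocks = nn.ModuleList()
        self.tds = nn.ModuleList()
        skip_channels = []
        for n in self.DOWN:
            db = DenseBlock(c, n, g, rng)
            self.down_blocks.append(db)
            c = db.out_channels
            skip_channels.append(c)
            self.tds.append(TransitionDown(c, rng))
        self.bottleneck = DenseBlock(c, self.BOTTLENECK, g, rng)
        new = self.BOTTLENECK * g
        self.tus = nn.ModuleList()
        self.up_blocks = nn.ModuleList()
        for n, skip_c in zip(self.UP, reversed(skip_channels)):
            self.tus.append(nn.ConvTranspose2d(new, new, 3, rng))
            db = DenseBlock(new + skip_c, n, g, rng)
            self.up_blocks.append(db)
            new = n * g
        self.head = nn.Conv2d(self.up_blocks[-1].out_channels, 1, 1, rng)

    def forward(self, x):
        x = self.stem(x)
        skips = []
        for db, td in zip(self.down_blocks, self.tds):
            full, _ = db(x)
            skips.append(full)
            x = td(full)
        _, new = self.bottleneck(x)
        for tu, db, skip in zip(self.tus, self.up_blocks, reversed(skips)):
            up = tu(new)
            full, new = db(nn.concat([up, skip], axis=1))
        return self.head(full)


# ---------------------------------------------------------------------------
# PPU-Net
# ---------------------------------------------------------------------------

class ResidualBlock(nn.Module):
    """Two conv3x3-BN(-ReLU) stages with a short (residual) skip.

    The block input is added to the second stage's pre-activation output
    (through a 1x1 projection when the channel counts differ) and the sum
    passes through the final ReLU.
    """

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.short = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        s = self.short(x) if self.short is not None else x
        return nn.relu(nn.add(h, s))


class PPUNet(Network):
    """Pyramid-pooling U-Net: 10/2/10 residual blocks, pyramid long skips."""

    family = "ppunet"
    LEVELS = 5
    BLOCKS_PER_LEVEL = 2

    def __init__(self, spec, rng):
        super().__init__(spec)
        w = spec.base_filters or 64
        proj = max(1, w // 4)  # 16 at the default width of 64
        self.enc = nn.ModuleList()
        c = spec.in_channels
        for _ in range(self.LEVELS):
            blocks = nn.ModuleList([ResidualBlock(c, w, rng),
                                    ResidualBlock(w, w, rng)])
            self.enc.append(blocks)
            c = w
        self.bottleneck = nn.ModuleList([ResidualBlock(w, w, rng),
                                         ResidualBlock(w, w, rng)])
        self.pyramids = nn.ModuleList([PyramidPooling(w, rng, proj)
                                       for _ in range(self.LEVELS)])
        skip_c = w + 5 * proj
        self.dec = nn.ModuleList()
        for _ in range(self.LEVELS):
            blocks = nn.ModuleList([ResidualBlock(w + skip_c, w, rng),
                                    ResidualBlock(w, w, rng)])
            self.dec.append(blocks)
        self.head = nn.Conv2d(w, 1, 1, rng)

    def forward(self, x):
        skips = []
        for blocks in self.enc:
            for b in blocks:
                x = b(x)
            skips.append(x)
            x = nn.maxpool2d(x)
        for b in self.bottleneck:
            x = b(x)
        for blocks, skip, pyramid in zip(self.dec, reversed(skips),
                                         reversed(list(self.pyramids))):
            up = nn.bilinear_resize(x, (x.data.shape[2] * 2, x.data.shape[3] * 2))
            x = nn.concat([up, pyramid(skip)], axis=1)
            for b in blocks:
                x = b(x)
        return self.head(x)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Build any family from its spec with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    cls = {"unet": UNet, "unetpp": UNetPP,
           "tiramisu": Tiramisu, "ppunet": PPUNet}[spec.family]
    return cls(spec, rng)


def build_unet(spec: ArchitectureSpec, seed: int = 0) -> Network:
    if spec.family != "unet":
        raise ValueError("spec.family must be 'unet'")
    return build(spec, seed)


def build_unet_variant(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """U-Net with ablation flags; identical to build_unet for empty flags."""
    return build_unet(spec, seed)


def build_unetpp(spec: ArchitectureSpec, seed: int = 0) -> Network:
    if spec.family != "unetpp":
        raise ValueError("spec.family must be 'unetpp'")
    return build(spec, seed)


def build_tiramisu(spec: ArchitectureSpec, seed: int = 0) -> Network:
    if spec.family != "tiramisu":
        raise ValueError("spec.family must be 'tiramisu'")
    return build(spec, seed)


def build_ppunet(spec: ArchitectureSpec, seed: int = 0) -> Network:
    if spec.family != "ppunet":
        raise ValueError("spec.family must be 'ppunet'")
    return build(spec, seed)


def default_spec(family: str, **overrides) -> ArchitectureSpec:
    return replace(ArchitectureSpec(family=family), **overrides) \
        if overrides else ArchitectureSpec(family=family)


def parameter_count_table(in_channels: int = 1) -> dict:
    """family -> trainable parameter count for the default specs."""
    return {fam: count_trainable_parameters(
        build(ArchitectureSpec(fam, in_channels=in_channels)))
        for fam in FAMILIES}
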