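# Methods

## Problem and scope

Nuclei must be found in transmitted-light (brightfield) micrographs, where
they appear as low-contrast textures rather than the bright blobs of a
fluorescence stain. The package implements the full stack for this task:
four encoder–decoder segmentation networks, the training strategies that
matter when annotated data are scarce, probability-map postprocessing,
pixel- and object-level evaluation, error-source attribution, experiment
runners, and a synthetic paired-scene generator that makes everything
testable on CPU without any image download.

## The networks

All four families are end-to-end convolutional encoder–decoders mapping a
grayscale patch (288 × 288 by default, 1–9 input channels) to a per-pixel
nucleus probability via a terminal 1 × 1 convolution and logistic
squashing. Trainable parameter totals count convolution kernels, biases
and batch-norm scale/shift; batch-norm running statistics are excluded.

**U-Net (baseline, 1.37 M parameters).** Five resolution levels of three
3 × 3 / 64-filter convolutions + ReLU per path; 2 × 2 max pooling and a
concatenation skip after every third convolution; a three-convolution
bottleneck. Upsampling is parameter-free bilinear interpolation: with
transposed convolutions the count moves further from the nominal 1.3 M,
and concatenation (rather than addition) skips are what place the total
at 1.37 M. Ablation flags: `double_skips` taps each encoder level twice
(after the 2nd and 3rd convolutions, widening the first decoder
convolution of each level to 192 input channels), `batch_norm` adds
2 × 64 parameters per normalized convolution, and `filter_pyramid` grows
the encoder widths 64→128→256→512 (mirrored in the decoder).

**U-Net++ (9.05 M).** A five-deep backbone with widths 32/64/128/256 and
a 512-filter bottleneck; two-convolution batch-normalized blocks; 2 × 2
max-pool down and 2 × 2 transposed-convolution up. The nested skip grid
X(i, j) re-convolves encoder features 3/2/1 times at the three upper
rows before they join the decoder; each node consumes all previous nodes
of its row plus an upsampling of the newest node one level below. The
`half_skip_convs` flag halves (rounding up) the intermediate node count
per row; the upsampling donor is then the newest available node below.

**Tiramisu (9.32 M).** A fully convolutional DenseNet: a 48-filter stem,
dense blocks of (4, 5, 7, 10, 12) layers down, 15 in the bottleneck and
(12, 10, 7, 5, 4) up, growth rate 16, each dense layer BN → ReLU →
3 × 3 convolution. Transition-down is BN → ReLU → 1 × 1 convolution →
2 × 2 max pool; the 1 × 1 convolution is part of the canonical design and
is required to reach the nominal ~9.4 M total (without it the network has
8.5 M parameters). Transition-up is a 3 × 3 stride-2 transposed
convolution carried by the preceding block's newly produced feature maps
only.

**PPU-Net (2.10 M).** The lightweight pyramid-pooling U-Net: five
resolution levels × two residual blocks per path plus a two-block
bottleneck, 64 filters throughout. A block is two 3 × 3 convolutions,
each followed by batch normalization and ReLU, with a short (residual)
skip from the block input to the second pre-activation — an identity
addition, through a 1 × 1 projection when channel counts differ. Every
long skip routes the encoder-level output through the pyramid pooling
module: average pooling at sizes 16/8/4/2/1 (stride = pool size), sixteen
1 × 1 convolutions + BN + ReLU per level, bilinear restoration to the
input resolution, and concatenation with the input (64 → 144 channels).
The bottleneck does not feed a pyramid-pooled skip. Pool windows are
edge-clipped and pool sizes clipped to the feature-map size, so the
+80-channel contract holds at every level (at a 288 input the coarsest
skip is 18 × 18, which no pyramid level divides). This 10/2/10 reading
reproduces the nominal ~2.1 M count almost exactly.

## Numerical engine

The networks run on a small reverse-mode automatic-differentiation engine
written on numpy (`brightnuc.nn`): a define-by-run tape over float32
NCHW arrays with im2col convolutions, stride-2 transposed convolutions,
batch normalization (momentum 0.9, eps 1e-5), 2 × 2 max pooling,
edge-clipped average pooling, exact-adjoint bilinear resizing, and a
numerically stable fused sigmoid/binary-cross-entropy head. Every
operation is verified against central finite differences in the test
suite. The optimizer is Adam with β = (0.9, 0.999) and ε = 1e-7.
Training runs on this engine are bit-reproducible on CPU under a fixed
seed. Model snapshots include batch-norm running statistics, so a
restored best-validation model predicts exactly as it did when recorded.

## Training protocol

Binary cross-entropy against (optionally smoothed) masks; label smoothing
maps targets {0, 1} → {s, 1 − s} with s ∈ [0, 0.5); per-family selected
factors are 0.05 (U-Net), 0.15 (U-Net++), 0.20 (Tiramisu) and 0.15
(PPU-Net). Augmentation is the lossless orientation orbit — horizontal
and vertical flips and rotations by 90°/180°/270° (counterclockwise,
numpy axis convention) — giving six oriented pairs per source pair per
epoch. Training patches are random crops re-sampled every step from a
seeded stream; the deterministic tiling grid (inward-shifted windows,
mean-blended stitching) is used only at inference.

The schedule: up to 500 epochs of 10 000 / batch-size optimizer steps;
"no improvement" means the validation loss fails to undercut the best by
1e-6; after 10 consecutive such epochs the learning rate is divided by
10, after 20 training stops, and the best-validation weights are
restored. Validation loss is computed on a fixed set of patches cropped
once with the run seed, keeping the schedule a pure function of the data
and seed (property-tested against an independent simulation).

The learning-rate range test sweeps a 100-point geometric grid from
1e-10 to 10, one optimizer step per rate, smooths the recorded losses
with a 5-point moving average, and proposes the rate with the largest
smoothed one-step loss drop (ties to the smallest rate; a NaN loss
truncates the sweep). Per-family defaults selected this way for
brightfield input: 1e-5, 1e-3, 5e-4, 5e-4.

## Postprocessing and evaluation

Probability maps are binarized at p ≥ 0.5, clustered into 8-connected
objects, objects smaller than 25 pixels removed (strict, on pre-fill
areas), then 4-connected background holes smaller than 25 pixels filled
with the enclosing object's label. Removal precedes filling so an
undersized ring cannot be rescued by its own filled hole; the pipeline
is idempotent. Labels are compacted in raster order of first pixels.

Object scoring is existence-based on the all-pairs IoU table (computed
in one joint-histogram pass): a ground-truth nucleus is detected at
threshold t if some predicted object reaches IoU ≥ t; unmatched
predictions are false positives; no one-to-one assignment is made, and
the merge/split counters (one event per offending object, IoU ≥ 0.1)
capture the pathologies that existence-based detection ignores. Missed
nuclei are those with best IoU < 0.6. Object F1 is reported on the
0.50–0.95 grid (step 0.05) and averaged. Every IoU gate uses ≥.
Balanced pixel accuracy is the mean of sensitivity and specificity, and
the pixel F1 of an empty prediction against an empty truth is defined
as 1. Object solidity uses the regionprops convex-hull convention
(pixel-center hull), under which convex rasterized shapes score exactly 1.

Error attribution: the FN/FP split of error pixels; the fraction of
error pixels inside annotated artifact regions together with the pixel-F1
gain from scoring outside them; and consensus label-noise estimation —
pixels where ≥ 4 of 5 models agree on the opposite of the ground truth,
reported as the flagged fraction of each model's own error pixels,
averaged over models (matching the "share of misclassified pixels"
framing).

## Synthetic scenes

The generator emulates the statistical regime of high-content nucleus
imaging, not its optics. Defaults mirror a 1080 × 1080 field at
0.59 µm/pixel with 353 nuclei (the `lncap_like` preset: 2556 × 2156,
~681 nuclei, larger radii at 0.325 µm/pixel). Nuclei are dart-thrown
ellipses (truncated-normal major radius, default 12 ± 3 px ≈ a 7–18 µm
diameter at 0.59 µm/px; uniform eccentricity up to 0.4 and orientation;
hard minimum center spacing 8 px with overlap permitted beyond it).
Ground truth rasterizes the ellipses with later-over-earlier z-order
(labels never merge; fully occluded nuclei are dropped from the realized
table). The fluorescence channel renders bright blobs plus Gaussian
noise. Brightfield renders each nucleus as a 2-px dark rim at
0.5·contrast below a mid-gray background with an interior lifted by
0.2·contrast — so the peak noiseless deviation defines the contrast
amplitude — plus, crucially, a faint cell body around every nucleus
(1.8× the nuclear radii, per-cell intensity offset uniform within
±0.3·contrast, additive across cells and excluded under the cell's own
nucleus). Cell bodies are what couple difficulty to density: where cells
crowd, their bodies overlap into clutter that mimics and masks nuclear
texture, reproducing the empirical penalty for dense fields. Out-of-focus
cells (default 10%) appear in fluorescence and ground truth but are
blurred (σ = 4) in every brightfield plane; focal stacks blur plane p by
|p − focus| · plane_blur_step; contamination artifacts are opaque
irregular blobs overwriting brightfield only, with a returned mask; a
modality shift displaces the brightfield render rigidly against the
ground truth. All randomness flows from one seed (per-image seeds are
derived by seed-sequence hashing), and identical configurations produce
bit-identical scenes.

What passing tests on these scenes does *not* show: performance on real
brightfield images. The renderer has no optics (no point-spread function,
no illumination field), no cell-cycle morphology, no texture inside
nuclei beyond a constant lift, and its artifacts are geometric blobs.
The synthetic results validate the machinery and reproduce directional
effects, not absolute real-data scores.

## Experiment runners and desk-scale choices

The runners (benchmark, training-set-size ablation with plain/smoothed/
augmented regimes and nested subsets, transfer with target-only or
interleaved two-domain fine-tuning, greedy focal-plane forward selection
with ⌈9/k⌉/⌊9/k⌋ channel replication and ties to the lowest plane index)
are pure functions of (data, plan, seed) and emit tidy DataFrames.

Experiments default to width-reduced networks (base_filters 16 for
U-Net/PPU-Net, 8 for the others, i.e. all widths scaled proportionally)
and 96 × 96 patches; `full=True` restores paper-scale widths and the 288
input. The test suite runs smaller still — 64–96 px scenes, width-8
networks, 180–300 optimizer steps per run, three seeds per directional
claim — sizes chosen so the full suite completes in minutes on one CPU
while each claim remains a real train-and-evaluate cycle. The density
analysis disables the out-of-focus error mode to isolate the manipulated
variable (out-of-focus misses add large per-image variance at low counts
without interacting with density).

## Known limitations

- The numpy engine is single-threaded apart from BLAS matmuls; it is
  meant for correctness and desk-scale experiments, not GPU-scale runs.
- `half_skip_convs` requires a choice of which skip-pathway nodes to
  drop; the chain-prefix reading implemented here is one of several
  defensible ones.
- The U-Net `filter_pyramid` variant's width ladder (64/128/256/512/512)
  is a reading of a variant described only loosely; only its qualitative
  contract (strictly more parameters, same convolution count) is relied
  upon.
- Consensus label-noise estimation assumes model errors are mostly
  independent of annotation noise; correlated model biases inflate it.
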