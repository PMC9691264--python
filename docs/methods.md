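# Methods

## Problem

The choroid is the vascular layer between retina and sclera; its thickness
and 3-D shape are biomarkers for high myopia, glaucoma, AMD and diabetic
retinopathy.  In OCT B-scans the upper choroid boundary (Bruch's membrane,
BM) is sharp, but the lower boundary (choroidal–scleral interface, CSI) is
low-contrast and ambiguous, so generic segmentation networks localise it
poorly.  `choroidseg` implements a boundary-enhanced segmentation network
plus the downstream thickness and 3-D morphometry, and a synthetic OCT
generator that supplies exact ground truth for testing all of it.

## Segmentation model

The backbone is a U-Net: `depth` encoder double-conv blocks
(conv3×3–BN–ReLU ×2, channels `base·2^i`) with 2×2 max pooling, a plain
double-conv bottleneck, and a mirrored decoder with nearest-neighbour
upsampling and skip concatenation; a 1×1 convolution and logistic produce
the choroid probability map.  A Boundary Enhancement Module (BEM) follows
every encoder and decoder block (not the bottleneck).  For block features
`f ∈ R^{w×h×c}` the BEM computes

- **FEB** — five parallel convolutions (1×1, and 3×3 at dilation rates
  1, 2, 4, 6), each to `max(4, c/4)` channels, concatenated, projected by a
  1×1 convolution and a logistic to a one-channel boundary point map `M`;
- **CEB** — global average pooling to a length-`c` vector, a kernel-3
  convolution across the channel axis (zero-padded so the length stays `c`),
  and a logistic, giving channel weights `N`;
- **BAB** — a 1×1 convolution to one channel, a logistic, then the
  activation `Q(x) = exp(−(x−0.5)²) + 1 − e^{−1/4}`, which is symmetric
  about 0.5, peaks there at `2 − e^{−1/4} ≈ 1.2212` (boundary-like
  responses) and equals exactly 1 at saturated interior/background
  responses;

and fuses them as `v = f + f·M·Q·N` (`M`, `Q` broadcast over channels, `N`
over space).  Since `M, N ∈ (0,1)` and `Q ∈ (1, 2−e^{−1/4}]`, the boost is
bounded: `|v − f| ≤ (2−e^{−1/4})·|f|`.  Each branch can be disabled
independently, which is how the ablation experiments are expressed; with
all three off the model is a plain U-Net.

With 4 encoder and 4 decoder BEM blocks around a bottleneck the input must
be divisible by `2^depth`; the network errors explicitly otherwise.

## Boundary supervision

From each ground-truth trace, `K` key points per boundary are selected —
uniformly in arc length by default, or at local maxima of the absolute
discrete curvature (ties leftmost, padded with uniform points).  The soft
point map holds, at pixel `(i, j)`,
`S = max_k exp(−((i−x_k)² + (j−y_k)²)/(2σ²))` — a maximum, not a sum, so
values stay in (0,1] and integer-coordinate key points score exactly 1.
Defaults `K = 10`, `σ = 5 px` are exposed in configuration.  Per-layer
targets for the FEB maps are obtained by block-max pooling of the
full-resolution map, which preserves the unit peaks at every scale
(re-rendering at low resolution would not).

## Objective

`L_total = 0.5·L_seg + 0.5·L_bp` where `L_seg` is binary cross entropy
(pixel mean by default, so the weights are image-size-free; an unnormalized
sum is available by flag) and `L_bp = L_gf + Σ_i MSE(M^i, M_gt^i)` over the
active BEMs.  The guided feature term `L_gf` concatenates the segmentation
map with the ground-truth soft point map, lifts the 2-channel stack to
three channels (third channel zero) with standard channel normalization,
passes both the ground-truth and predicted stacks through a frozen
convolutional feature hierarchy, and sums `1/N_i`-normalized L1 distances
at the first four pooled stages.  The reference extractor for this role is
an ImageNet-pretrained VGG-19; pretrained weights are an external asset,
so the loss accepts any frozen extractor and defaults to a small
deterministic randomly-initialised one (seeded, never trained).  The
guidance contract — zero at identity, nonnegative, gradients flowing only
to the prediction — is weight-independent and is what the tests verify.
BM and CSI points are merged into a single supervision map, matching the
single map symbol in the loss definition.

## Numerical engine

No GPU tensor framework is assumed: the network runs on a small
reverse-mode autodiff engine over float32 numpy arrays
(`choroidseg.nn`), with stride-1 dilated convolution evaluated as one BLAS
matmul per kernel tap, batch normalization composed from differentiable
primitives, first-occurrence-argmax 2×2 pooling, and Adam.  Backward
closures never capture their output node, so tapes are cycle-free and are
reclaimed by reference counting.  All gradients are verified against
central finite differences in the test suite (float32 limits the agreement
to ~1e-3 relative; kink points of relu/maxpool are avoided by
construction in those checks).

Training uses Adam at learning rate 5e-4 with batch size 8 (the reference
protocol).  Predictions are thresholded at 0.5.

## Synthetic data

The generator renders three constant bands — retina 0.8, choroid 0.5,
sclera `0.5 − 0.3·csi_contrast` on a [0,1] scale — between two smooth
boundary curves (sums of low-frequency random-phase sinusoids, bounded by
an amplitude parameter; across a volume the curves come from a shared 2-D
low-frequency field so adjacent slices co-vary).  Speckle is multiplicative
gamma noise with unit mean (shape `k`; `k → ∞` recovers the noiseless
render), after which intensities are quantized to the configured bit depth
(6–16).  Masks use the half-open convention `⌈bm⌉ ≤ row < ⌈csi⌉`, and the
boundary extractor uses the same convention, so mask→trace round trips are
sub-pixel by construction.  `csi_contrast = 0` makes the CSI genuinely
invisible, for robustness experiments.

Default study conditions: 512×256 B-scans at 4 µm axial / 6 µm lateral
sampling, 230 µm mean choroidal thickness (a typical healthy macular
value), ±40 µm smooth thickness modulation, ±8 px boundary undulation,
speckle shape 8, 8-bit quantization.  The desk-scale experiment profile
uses 64×64 scans at 10 µm axial sampling with 200 µm (20 px) thickness,
which keeps a full training run on one CPU core in minutes: 200 Adam steps
on 200 scans with a depth-4, 16-channel network, evaluated on 50 held-out
scans.  What the generator does **not** emulate: vessel shadows and
intra-band texture, pathology, depth-dependent signal roll-off, motion
artifacts, or device-calibrated SNR (no quantitative description of real
acquisitions was available to calibrate against).  Passing tests therefore
demonstrate correctness of the algorithms and trainability on controlled
contrast/noise, not clinical-grade performance.

## Evaluation metrics

Region metrics (Dice, IoU, accuracy, sensitivity) come from exact pixel
confusion counts; an empty prediction matching an empty ground truth scores
1 by convention, other zero denominators score 0 with a warning.  Boundary
traces are read off predicted masks after keeping the largest 4-connected
component (configurable off): BM is the topmost foreground row per column,
CSI the bottommost + 1.  AUSDE is the mean per-column |row difference| of a
boundary; TD the mean per-column absolute thickness difference.  Columns
missing in either trace are excluded and the joint coverage reported, so
fragmentary predictions are measurable rather than undefined.  TD ≤
AUSDE(BM) + AUSDE(CSI) always (triangle inequality) — a tested invariant.

## Morphometry

Thickness at (slice, column) is `(csi − bm)·axial_spacing` (µm).  ETDRS
subfields are drawn directly in the physical (mm) coordinates of each grid
cell — circles of 1/3/6 mm diameter around the fovea (taken as the grid
center unless overridden, matching macula-centered acquisition), annuli
split into superior/inferior/nasal/temporal quadrants along the ±45°
diagonals; for OD the nasal side is the +column half, mirrored for OS.
Because the 9 masks partition the 6 mm disk exactly, the pixel-count
weighted subfield mean reproduces the disk mean; working in mm coordinates
keeps circles circular on anisotropic grids without resampling error.
Missing cells are excluded per subfield with coverage reported.

3-D features: boundary surfaces become point clouds / height fields in mm
(x = column·lateral, y = slice·slice spacing, z = row·axial).  Volume is a
rectangle-rule sum of thickness × cell area over an axis-aligned
fovea-centered ROI (default 3×3 mm, read as a box).  Surface area
triangulates each grid cell into two triangles (cells touching missing
vertices are skipped).  Curvature is the mean curvature of a local
least-squares quadric fit in sliding windows (default 1 mm, stride half a
window), averaged as absolute values — "curvature" is otherwise undefined
for a discrete cloud, and quadric fits are robust at grid scale.  "Inner"
volume/area follow the convention that the choroid interior is bounded by
BM above and CSI below, with the inner surface area computed on the CSI
height field (the BM area is reported alongside).  Group comparisons use
Welch's two-sample t-test (unequal variances, the safe default) with the
95% CI of the mean difference; single-subject groups are reported
means-only and flagged.

## Cross-validation and reproducibility

`make_folds` produces seeded 4-fold partitions, grouping all slices of a
volume into the same fold when volume ids are given.  Every CLI run writes
its resolved configuration (with hash and seed) next to its outputs.  All
stochastic stages derive from a single top-level seed; repeated runs are
bit-identical.

## Known limitations

- The point-selection rule behind the soft maps is re-specified here
  (uniform / curvature strategies); the exact original rule, and the values
  of K and σ used in the reference experiments, are not public.
- The default perceptual extractor is random, not pretrained; supervision
  strength differs from a pretrained hierarchy even though the contract is
  the same.
- CPU-scale training (64×64, 200 steps) shows recovery on synthetic data
  only; no claim is made about clinical images.
- Mean curvature windows shorter than ~10 grid cells are noisy; the CLI
  clamps the ROI to the grid but not the curvature window.
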