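# Methods

This note documents the model implemented by `m3seg`, the choices behind
it, and what the synthetic test-bed does and does not establish.

## Model

`m3seg` implements a hybrid U-shaped segmentation network for 2-D medical
images. A residual convolutional stem extracts features at 1/2, 1/4 and
1/8 resolution; the 1/8 feature map is linearly projected into a token
sequence that a stack of transformer blocks refines; a progressive decoder
restores full resolution, fusing gated skip features on the way up; a 1×1
head emits per-pixel class logits. Four attention/gating mechanisms
distinguish the architecture from a plain hybrid U-Net:

**Distance-biased self-attention.** Within each encoder block, multi-head
self-attention logits are penalised by a normalised Manhattan distance on
the token grid:

    Attn(Q, K, V) = softmax(QKᵀ/√d_k − λ·D) V,
    D_ij = (|x_i − x_j| + |y_i − y_j|) / (H + W),

with one learnable scalar λ per head, initialised to 1. The bias is a
locality prior: spatially adjacent tokens receive larger initial attention
weights, while λ lets training anneal the constraint per head (λ → 0
recovers vanilla attention exactly; the suite asserts this bitwise). λ is
unconstrained in sign during training. Token enumeration is row-major from
the top-left, 0-based.

**Multi-scale gate attention (encoder).** Channels are split into G groups
(default 8; it must divide the hidden dimension). Per group: a 3×3
depthwise convolution extracts local structure; directional average/max
pooling strips along each axis are reduced by a shared 1×1 convolution and
broadcast-added into a sigmoid spatial map that gates the depthwise
features; a cross-spatial block then couples a group-normalised stream
with a channel-softmaxed global-average descriptor through matrix products
in both pairings, and the summed maps re-weight the *original* group input
through a sigmoid. The published description leaves the pooling shapes and
the cross-spatial matrix shapes open; the shapes above follow
coordinate-attention and cross-spatial-learning conventions. The group
count of the internal group norm is `gcd(G, channels-per-group)`. Because
the final gate is a sigmoid, the module can only attenuate — `|Y| ≤ |X|`
elementwise is asserted as a property.

**Multi-kernel gated skip connections.** Each skip feature X passes through
three independent 3×3 group-convolution branches (group count `gcd(4, C)`;
the description leaves it open) with batch normalisation; the branch sum is
ReLU6-activated, compressed to one channel by a 1×1 convolution and
squashed into a sigmoid map A that re-weights X identically across
channels. All three kernels are 3×3 — the textual definition is taken as
authoritative over the block diagram, which may depict heterogeneous
kernels. The gate consumes only the skip feature (no decoder-side signal).
Batch norms support a deterministic identity mode used by fixtures.

**Multi-scale selective attention (decoder).** Four depthwise-separable
branches with kernels 3/5/7/9 (ReLU, then squeeze-and-excitation with
reduction 16, floor 4), concatenated and fused to C channels by a 1×1
convolution; a single linear-complexity attention layer then runs over the
H·W spatial tokens of the fused map (post-fusion rather than per-branch:
the branches are fused first, then attended); the attention output is
concatenated with the module input and projected back to C channels.

**Linear (performer) attention.** Softmax attention is approximated with a
positive random-feature map so the cost is O(N·m·d) and no N×N matrix is
materialised:

    out = D⁻¹ ϕ(Q)(ϕ(K)ᵀ V),   D = diag(ϕ(Q) ϕ(K)ᵀ 1).

ϕ is the positive softmax-kernel map, `exp(w·x − |x|²/2)`, on inputs
pre-scaled by d^(−1/4), with Gaussian projections drawn in antithetic ±
pairs — each feature alone is an unbiased softmax-kernel estimator, and
pairing halves the effective variance at no cost. The projection is drawn
once at construction from a seedable generator, so the forward pass is
deterministic. Per-query-row and global log-space stabilisers (which
cancel in the normalisation) guard against overflow; a degenerate
normaliser raises rather than producing NaN. Measured accuracy against the
exact O(N²) oracle on unit-norm query/key rows: median relative Frobenius
error ≈10% at m=16 falling to ≈1.4% at m=1024 (N=64, d=16), and ≈1.1% at
m=4096 (N=32, d=8). Unit-norm rows are used in the oracle comparisons to
isolate approximation quality from input scale: for standard-normal rows
the positive-feature estimator's variance term exp(|q'|²+|k'|²) makes the
error of *any* variant of this map approach 100% at these dimensions. The
default m is 256.

## Assembly choices that the source description leaves open

* **Encoder block composition**: `Y1 = X + Attn(LN(MSGA(X)))`,
  `Y2 = Y1 + MLP(LN(Y1))` — the residual source for the attention
  sub-block is the block input (standard pre-norm style).
* **CNN stem**: a three-stage residual backbone with widths w/2w/4w
  (`stem_width` w = 64 for the base preset) and group-norm; no pretrained
  weights. Parameter-count parity with any particular published figure is
  therefore reported, not asserted.
* **Patch embedding**: a strided convolution on the 1/8 stem features with
  stride `patch_size/8`, plus a learnable absolute position embedding
  (the Manhattan bias replaces *relative* position tables, not the
  absolute embedding).
* **Decoder**: `log2(patch_size)` up-stages (bilinear 2×, corner-aligned
  sampling off), channels (256, 128, 64, 16) for 16-px patches; gated
  skips enter the first `num_skips` stages whose resolution matches a stem
  skip; the final skipless stage is a plain upsample-convolution (the
  selective-attention refinement runs on skip-fusing stages). Masks are
  never interpolated bilinearly anywhere.
* **MLP activation**: GELU (exact, erf-based), hidden width 4·D.

## Objective and metrics

Training minimises `0.5·CE + 0.5·Dice`. CE is the mean pixel
cross-entropy; Dice averages the soft overlap over the C−1 foreground
classes (background excluded), with smoothing ε = 1e−5 in numerator and
denominator. Probabilities are clamped at 1e−12 inside the log so exact
zeros never produce NaN.

Evaluation reports DSC (×100), HD95 (mm) and IOU per foreground class.
A voxel is a boundary voxel if it is foreground with at least one
background face-neighbour (image edges count as background). HD95 is the
95th percentile of the pooled union of both directed boundary-distance
sets, computed with an exact Euclidean distance transform on the
spacing-scaled grid. HD95 of an empty mask is undefined: it is excluded
from means and the exclusion count is reported, never imputed. Volume
evaluation can run per-slice (2-D) or on the stacked volume (3-D); a
one-slice "volume" is evaluated in-plane so the two modes agree there.

## Data handling

CT volumes are windowed to [−125, 275] HU and mapped affinely to [0, 1];
photographic inputs (flagged non-HU) bypass the windowing. All images are
resized to the model's input size (224 default) — bilinear for images,
nearest-neighbour for masks so labels stay crisp and the output label set
is a subset of the input's.

Training augmentation is on-the-fly; each draw is a pure function of
(policy seed, draw seed). Horizontal flip has probability 0.5 and rotation
is limited to ±20°; those two magnitudes are the stated policy. The
remaining magnitudes are package defaults chosen conservatively within the
named transform families: joint affine (p 0.5) with translation ≤ 10% of
the side and scale in [0.9, 1.1]; elastic deformation (p 0.3, α = 30 px,
σ = 5 px, nearest-neighbour for the mask); up to 2 occlusion holes of
≤ 16 px (p 0.3, image only); brightness/contrast ± 0.2 (p 0.5); Gaussian
noise σ ≤ 0.02 of the intensity range (p 0.3); CLAHE with clip 2.0 on the
conventional scale (p 0.2). All are overridable in the YAML config.
Augmentation is strictly train-time; evaluation and prediction paths are
deterministic.

The optimiser is SGD (lr 0.01, momentum 0.9, weight decay 1e−4) with
polynomial decay `lr₀·(1 − it/max_it)^0.9`. Batches are uniform random
draws with replacement over the training slices; per-iteration seeds are
derived statelessly from (master seed, iteration), so resuming from a
checkpoint reproduces the uninterrupted run bitwise.

## Synthetic phantoms

The phantom generator emulates the statistical shape of abdominal CT
slices: a dark noisy background carrying several "organ" blobs — randomly
deformed, rotated ellipses with radial Fourier wobble — whose areas are
log-spaced from 15% down to 0.4% of the canvas (drawn largest-first with
bounded overlap, so each phantom contains both a >10% and a <1%
structure). Foreground mean intensities are spread over [0.35, 0.9] with
one deliberately low-contrast pair (gap 0.05); additive Gaussian noise
defaults to σ = 0.03. The mask equals the blob geometry exactly and every
label is present. Defaults are 224-px canvases with 9 classes (background
plus eight organs, mirroring the multi-organ CT setting); tests and desk
training use 64-px, 4-class phantoms.

What the phantoms do **not** emulate: anatomical shape priors and
inter-organ spatial relationships, partial-volume and reconstruction
artefacts, intensity inhomogeneity within an organ, and inter-subject
variability. Passing the end-to-end test therefore demonstrates that all
modules are differentiable, jointly trainable and capable of fitting
multi-class, multi-scale, low-contrast targets — it is a learnability and
correctness statement, not a claim about clinical segmentation accuracy.

## Numerical and testing choices

* All arithmetic is float64 on a purpose-built reverse-mode autodiff core
  (`autodiff.py`); every primitive's gradient is verified against central
  differences in the test-suite.
* Softmax subtracts a detached row-max (exact, since softmax is
  shift-invariant). Attention row sums are checked to 1e−6.
* Ties in max-pooling route the gradient to the first maximiser.
* Group-norm group counts fall back to the largest divisor ≤ 8 when 8 does
  not divide the channel count.
* The desk-scale problem sizes used by the automated checks — a tiny
  preset (64-px inputs, hidden dim 64, depth 2, G=4, m=64), 4 phantoms,
  early-stopped training (typically 200–400 iterations), and 20-draw
  medians for the kernel-attention comparisons — were chosen so the whole
  suite exercises every module meaningfully on a single CPU.

## Known limitations

* No 3-D volumetric model and no pretrained backbones; the "large" preset
  (hidden dim 1024, depth 24) is supported in configuration but not
  exercised by training runs here.
* Benchmark-dataset results (multi-organ CT, endoscopy, radiography,
  dermoscopy) require dataset downloads and GPU-scale training and are out
  of scope; nothing here asserts parity with published benchmark tables.
* The kernel-attention accuracy figures above are for the default
  antithetic Gaussian map; orthogonal-feature variants are deliberately
  not implemented.
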