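# Methods

This note documents the models, the preprocessing chain, the synthetic data,
and the numerical and design choices behind them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

Given a 2-D CT slice, predict a binary mask of lung-nodule pixels. The
pipeline has three stages: (1) lung-field extraction, which restricts the
search space to the lungs; (2) a fully convolutional segmentation network
emitting a per-pixel nodule probability; (3) thresholding and overlap-based
evaluation against ground truth.

## Preprocessing chain

Order of operations on one slice: optional Hounsfield clamp →
standardization → median filter → anisotropic diffusion → K-means
thresholding → morphological opening → lung-region selection → mask/ROI
multiplication.

* **Hounsfield clamp** `[−1000, 400]` (applied only when the caller marks
  the input as HU, e.g. DICOM): removes out-of-body extremes; air ≈ −1000,
  soft tissue < 400.
* **Standardization**: subtract the mean, divide by the population standard
  deviation. A constant image is rejected as degenerate.
* **Median filter**, default 3×3, reflection-padded: robust outlier
  removal that preserves edges.
* **Perona–Malik diffusion**: explicit 4-neighbour updates
  `I += γ Σ c(∇I) ∇I` with conduction `exp(−(∇I/κ)²)` (or the rational
  form). Defaults: 10 iterations, κ = 30, γ = 0.1; γ ≤ 0.25 is enforced as
  the 4-neighbour stability bound. Constant images are exact fixed points
  and variance never increases — both are tested.
* **K-means thresholding**: 1-D K-means (k = 2, k-means++, 10 restarts,
  fixed seed) on intensities; centroids are sorted, the threshold is the
  midpoint across the largest centroid gap, and clusters below it (air and
  lung parenchyma, which are dark on CT) become the foreground candidate
  mask.
* **Opening** with a disk of radius 2 removes speckle.
* **Region selection**: 8-connected components; components whose bounding
  box comes within 2 px of the border (the air surrounding the body) or
  smaller than 0.5 % of the image are dropped; the two largest survivors
  are the lungs. Two post-steps make the mask anatomically usable: a
  closing (disk 5) that smooths bays cut into the boundary by bright
  juxtapleural nodules, and hole filling, because interior nodules are
  brighter than parenchyma and would otherwise be excluded from their own
  search region. Both are configurable and on by default.
* **ROI extraction**: the selected mask is dilated (disk 5) and multiplied
  with the slice; the *undilated* mask is returned as the lung mask so it
  remains comparable to ground truth.

Nodule ground truth comes from multi-reader contours: per reader, contours
with equivalent diameter `2·√(area/π)·spacing` below 3 mm are dropped (the
conventional full-annotation threshold), the remaining polygons are filled,
and a pixel becomes nodule when at least a consensus fraction (default 50 %)
of readers marked it.

## Architectures

All three networks map `(B, 1, H, W)` inputs to same-sized probability maps
through a final 1×1 convolution and sigmoid.

**Multi-scale UNet.** Encoder widths (32, 64, 128, 256), bottleneck 512,
2×2 max-pool downsampling; each stage is a multi-scale block: parallel
same-padded 3×3 and 7×7 convolutions (each batch-normalized and activated),
concatenated and fused by a 1×1 convolution. The decoder upsamples by
2×2 transposed convolutions and concatenates the encoder skip at each level;
decoder blocks use half the mirrored encoder width (128, 64, 32, 16) — the
light-decoder convention of modern segmentation libraries, keeping the model
deliberately inexpensive. Input sides must be divisible by 16.

**ACB-UNet.** Five encoder levels of widths (32, 64, 128, 256, 512), each an
asymmetric convolution block (ACB): the sum of 3×3, 1×3 and 3×1 branches,
then batch normalization and activation. The branch sum is algebraically a
single 3×3 convolution whose kernel is the square kernel plus the horizontal
kernel in its middle row and the vertical kernel in its middle column; this
fused-kernel identity is verified to 1e-5 in the tests. Decoder maps are
built by multi-scale skip fusion: at level j, encoder maps from shallower
levels are max-pooled to level-j resolution, 1×1-projected to the level
width (a sum across unequal channel counts is otherwise undefined — the
projection is this package's resolution of that gap), summed with the
level-j encoder map and passed through an ACB; deeper decoder maps are
upsampled by cascades of stride-2 transposed convolutions whose first stage
reduces channels (so high-resolution stages stay cheap), summed, and passed
through a second ACB; the two branches are concatenated and a channel
attention block (ChAB) emits the decoder map. The deepest decoder map is the
deepest encoder map unchanged. ChAB reduces the concatenated input to the
level width with a 1×1 convolution (128 filters at level 3), squeezes global
average- and max-pooled descriptors to 1/16 of that width through separate
per-branch squeeze/restore convolutions, and multiplies the sigmoid of their
sum with the reduced map. Post-upsampling ACBs also counteract the
checkerboard artifact of transposed convolutions.

**FPN with linear attention.** ResNet-34 (stage widths 64/128/256/512 with
3/4/6/3 basic blocks, trained from scratch; first convolution adapted to
one input channel) provides bottom-up maps F2–F5 at 1/4, 1/8, 1/16, 1/32 of
the input; the stride-2 stem output F1 is never kept. The top-down pathway
applies 1×1 lateral convolutions to d = 64 channels, merges by
nearest-neighbour 2× upsampling and addition, and smooths each merged map
with a 3×3 anti-aliasing convolution (applied to the coarsest map too, so
P5 exists for aggregation). The aggregation module upsamples P3–P5 to P2's
resolution, concatenates (4d = 256 channels), fuses with a 1×1 convolution,
and refines the flattened positions with single-head linear attention
(1×1-convolution QKV, embedding 256), adding the refined map residually to
the concatenated features. The head is a 3×3 convolution, 4× bilinear
upsampling to input size, and the 1×1/sigmoid output. Input sides must be
divisible by 32.

**Linear attention.** With q̂, k̂ the L2-normalized query/key rows,

    out_x = ( Σ_y v_y + q̂_xᵀ S ) / ( M + q̂_xᵀ z + ε ),
    S = Σ_y k̂_y v_yᵀ,   z = Σ_y k̂_y,

computed once and reused for all queries; no M×M array is ever formed.
Normalization bounds q̂ᵀk̂ ≥ −1, so the implicit weights
`(1 + q̂ᵀk̂_y)/(M + q̂ᵀz)` are non-negative and sum to one. ε = 1e-6 guards
the adversarial all-antipodal case in which the denominator would vanish;
zero query/key rows are rejected with an error naming the row. The exact
softmax form is kept alongside as the O(M²) reference. One consequence of
the normalization, verified numerically: linear attention is *scale
invariant* in Q and K, so only the softmax form flattens toward the
column-mean of V as similarities are scaled down.

**Activations.** A registry of SELU, ELU, GELU (exact erf form, with the
tanh surrogate `erf(i/√2) ≈ tanh(√(2/π)(i + 0.044715 i³))` as a variant,
agreeing within 5e-3 on [−5, 5]), Mish (`x·tanh(softplus x)`), Swish
(`x·σ(x)`), ReLU and LeakyReLU. Default activations per architecture follow
the best-performing configuration for each: LeakyReLU for the multi-scale
UNet, ELU for the ACB-UNet, GELU for the FPN.

## Training and evaluation

Loss: `0.5·BCE + 0.5·(1 − (2Σpg + s)/(Σp + Σg + s))` with dice smoothing
s = 1; probabilities are clipped to [1e-7, 1−1e-7] inside the loss only.
Optimizer: Adam, learning rate 1e-5, weight decay 1e-4 (added to the
gradient), batch size 8, 200 epochs by default. Splits are 80/10/10 by
largest-remainder rounding, seeded; phantom splits are per-sample (for real
data, split at patient level to avoid slice leakage). The best-validation-DSC
weights are retained. Training aborts on a non-finite loss.

Metrics: precision, recall, accuracy, DSC and IoU from pixel confusion
counts; DSC = 2·IoU/(1+IoU) holds exactly by construction. When a
denominator is empty (e.g. both masks empty), the metric is reported as 1 —
perfect agreement on absence — and flagged. Per-image means are the default
aggregation; pooled pixel counts are available as an option. Binarization
threshold 0.5.

## Synthetic phantoms

A phantom is a piecewise-constant slice: background 0.05, body ellipse 0.70
(semi-axes 0.40/0.46 of the side), two lung ellipses 0.25 (vertically
elongated, semi-axes 0.27/0.13, centered at 0.32/0.68 of the width), and
0–5 bright elliptical nodules at 0.65 strictly inside the lungs, with
additive Gaussian noise σ = 0.02. Intensities must satisfy background <
lung < nodule ≤ body. Nodule radii default to 2–8 px at the 128-px default
size and scale down proportionally for smaller phantoms (`scaled_config`);
disjoint placement keeps an 8-connectivity gap so component counts equal
nodule counts, and an optional juxtapleural mode lets nodules touch the
pleural boundary. Every sample is a pure function of its seed.

What the phantoms do *not* emulate: scanner physics (beam hardening,
reconstruction kernels), vasculature, ground-glass texture, 3-D continuity.
Passing tests therefore demonstrate correctness of the implementation and
the presence of a learning signal, not clinical performance.

## Numerical engine

The networks run on a small numpy autograd engine (float32): define-by-run
reverse-mode differentiation with convolution (channels-last per-tap GEMMs;
a full-image variant on large maps where padding overhead is negligible),
non-overlapping transposed convolution (kernel = stride, which also avoids
checkerboard overlap), max pooling, global pooling, nearest/bilinear
upsampling (align-corners-false), a fused batch normalization (ε = 1e-5,
momentum 0.1, biased variance), and Adam. All primitives are validated
against central finite differences in the test suite. Training-mode batch
norm uses batch statistics; evaluation mode uses running averages — an
untrained network evaluated before any training step can therefore saturate
its sigmoid in float32, which is the familiar behavior of mainstream
frameworks, not an error.

## Scaled-down study conditions

The end-to-end checks train all three architectures for 15 epochs on 128
phantoms of 64×64 px (batch 8, Adam 1e-5, weight decay 1e-4) with 16
validation and 16 held-out phantoms, verifying that the training loss falls
and that the trained FPN-with-linear-attention model beats its untrained
twin's mean DSC on the held-out set. These sizes are the package's chosen
desk-scale study conditions; full-scale experiments on real CT (512×512
slices, hundreds of epochs) are out of scope here and would use the same
code paths with larger configuration values.

## Known limitations

* 2-D slices only; no 3-D context or slice aggregation.
* The LIDC-style XML parser is best-effort (namespace-agnostic element
  matching); the simplified JSON dialect is the first-class annotation
  format.
* CPU-only: wall-clock cost grows quickly with image size; the default
  configurations are sized for a single core.
* No learning-rate schedules, early stopping (beyond best-checkpoint
  retention), mixed precision or data augmentation.
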