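# Methods

## The model

`leafswin` implements a two-channel hierarchical vision transformer for
classifying leaf-disease photographs of woody (ligneous) fruit crops.  Both
channels are structurally identical shifted-window transformers with **no
weight sharing**; they differ only in input:

- the **upper channel** receives the raw RGB image;
- the **lower channel** receives an **edge image** produced by a trainable
  Sobel layer: BT.601 grayscale conversion, cross-correlation with the 3×3
  kernel pair

  ```
  G_x = [[+1, 0, -1],       G_y = G_xᵀ = [[+1, +2, +1],
         [+2, 0, -2],                     [ 0,  0,  0],
         [+1, 0, -1]]                     [-1, -2, -1]]
  ```

  followed by the gradient magnitude √(G_x²+G_y²), per-image max rescaling to
  [0, 1], and replication into three channels so both channels share one
  patch-embedding geometry.  The kernels are ordinary parameters initialized
  to the classical operator; gradients flow through the whole edge map, so
  back-propagation may refine them (`trainable_sobel=False` freezes them for
  the fixed-operator ablation).

Each channel partitions the (default 224×224) image into non-overlapping 4×4
patches — 48 features per token — embeds them linearly into C = 96
dimensions, and runs four stages of depths 2/2/6/2 with heads 3/6/12/24.
Blocks follow the pre-norm residual recurrence

```
x ← x + (S)W-MSA(LN(x))
x ← x + MLP(LN(x))
```

alternating regular-window attention (W-MSA) and shifted-window attention
(SW-MSA, cyclic shift ⌊M/2⌋ = 3 with a provenance mask that zeroes attention
between tokens from different pre-shift windows).  The window size is M = 7.
Patch merging between stages concatenates 2×2 token neighborhoods,
layer-normalizes, and linearly reduces 4C → 2C, so grids shrink
56 → 28 → 14 → 7 while channels double 96 → 192 → 384 → 768.  In stage 4 the
window covers the whole 7×7 grid, where a cyclic shift is a pure token
permutation; shifted blocks there use shift 0 (standard practice).

After a final layer norm, each channel is globally average-pooled over space
to an 8C = 768-vector.  The two vectors are concatenated (upper first),
mapped by one fully-connected head to 22 logits, and softmax-normalized.
Training minimizes cross-entropy, with soft-label support for Mixup/CutMix.

Window-restricted attention is what makes the hierarchy affordable: with
h×w tokens of width C,

```
Ω(MSA)   = 4hwC² + 2(hw)²C        (global attention, quadratic in hw)
Ω(W-MSA) = 4hwC² + 2M²hwC        (windowed attention, linear in hw)
```

`complexity_estimate` evaluates both forms exactly.

## Numerical core

No tensor framework with automatic differentiation is part of the package's
dependency set; the model runs on a purpose-built reverse-mode autodiff core
(`leafswin.autodiff`) over NumPy.  Every primitive (broadcasted arithmetic,
batched matmul, reductions, gather/roll/reshape, GELU, softmax) carries an
exact vector-Jacobian product, verified against central finite differences in
the test suite, including end-to-end from the loss to the Sobel kernels.
Parameters are float32; float64 flows through unchanged for gradient checks.

Numerical choices worth knowing:

- **Edge magnitude**: computed as √(g_x²+g_y²+ε²)−ε with ε = 10⁻⁶, which is
  differentiable at zero response and still exactly zero on a flat image; the
  per-image maximum used for rescaling is itself differentiated (ties share
  the subgradient), and the denominator adds 10⁻⁸ so a zero map stays zero.
- **Replicate padding** for the 3×3 correlation keeps response maps the input
  size without the spurious frame edges zero-padding would create.
- **Cross-correlation**, not flipped convolution, matching deep-learning
  convention; the G_x = G_yᵀ relation is preserved either way.
- **Masked attention** adds −∞ to blocked logits before the softmax, so
  cross-provenance attention mass is exactly 0, not merely small.
- **Shared input standardization**: both channels' inputs (raw image and
  [0, 1] edge image) are standardized as (x − 0.5)/0.25 before patch
  embedding.  Without it, between-image feature variance at initialization is
  tiny and small-scale training stalls at the uniform-prediction saddle.
- **Zero-initialized head**: an untrained model predicts exactly the uniform
  distribution, and early training skips the collapse-to-uniform phase.
- **Stochastic depth** is configurable (`drop_path_rate`) and defaults to 0,
  keeping forward passes deterministic.
- Argmax ties in evaluation resolve to the lowest class index.

## Training protocol

Defaults mirror the reference protocol: batch size 8, Adam (β = 0.9/0.999,
ε = 10⁻⁸) at learning rate 10⁻⁴, 100 epochs, stratified 10-fold
cross-validation (folds over the training set; the held-out test tree is for
final reporting).  The best-by-validation-accuracy checkpoint is retained,
ties resolved to the latest epoch.  All randomness (shuffling, augmentation,
initialization) flows through explicit seeded generators, so runs are
bit-reproducible.

Augmentation (training only, applied to the raw image *before* the edge
channel is computed so both channels stay geometrically consistent):
horizontal RandomFlip (p = 0.5), ColorJitter (brightness/contrast/saturation
0.4, hue 0.1, torchvision-style factor ranges), and per batch at most one of
Mixup (α = 0.8) or CutMix (α = 1.0), chosen with equal probability half the
time.  CutMix recomputes the label coefficient from the exact border-clipped
box area.  The augmentation hyper-parameters are the common defaults for
hierarchical-transformer training; the protocol source names only the four
techniques.

`load_pretrained` imports externally distributed Swin-T ImageNet weights
(timm-style parameter names) into either or both channels through an explicit
mapping table; torch `(out, in)` linear weights are transposed, and the
patch-embed convolution `(C, 3, 4, 4)` is reordered to the flattened-patch
layout `(48, C)` (token order: row, column, then RGB).  The classification
head and the Sobel kernels are never taken from an archive.  Whether the edge
channel should also start from ImageNet weights is genuinely open; the
`channel` selector supports `upper`, `lower` and `both`.

## Metrics

From the confusion matrix (rows = truth), per-class one-vs-rest counts give
accuracy, precision, recall and F1 = 2PR/(P+R).  Headline numbers are
macro-averages (the usual convention for imbalanced multi-class benchmarks);
micro-averages are reported alongside, and for pooled counts
micro-precision = micro-recall = micro-F1 = trace/total.  Ratios with zero
denominators are reported as 0 and flagged.

## Synthetic data

Real photographs of the 22 classes cannot ship with the package, so
`leafswin.data` renders seeded stand-ins that preserve what the model is
sensitive to: an elliptical, randomly rotated leaf blade with a
species-specific hue on a textured soil-like background; for diseased
classes, lesions placed by a seeded point process **uniformly over the whole
blade** (affected areas dispersed across the leaf, not confined to one spot).
Severity is encoded the way real symptoms progress: *general* grades get
~15 lesions (radius 2–5% of the image side) and a 0.06 hue drift toward
yellow (chlorosis); *serious* grades get ~35 larger lesions (3–8%) and a 0.13
drift.  Healthy classes place zero lesions by construction.  The class
manifest reproduces the source bookkeeping exactly: 22 classes, 11,603
training and 1,668 testing images; `generate_dataset(scale=...)` writes
`ceil(scale × count)` PNGs per class in image-folder layout.

What the generator does **not** emulate: real leaf venation and texture
statistics, lighting and background clutter, intra-class variability of
actual field photographs, and the fine-grained confusions between visually
similar disease grades.  Tests passing on this data therefore demonstrate
that the architecture, gradients, augmentation and bookkeeping are correct
and that the pipeline can fit a learnable signal — not that the model
reaches any particular accuracy on real ligneous leaf photographs.

## Desk-scale problem sizes

The package's own verification runs use reduced sizes chosen to keep the
suite comfortably reproducible on a single CPU: unit tests exercise an
8×8/one-stage configuration; the overfitting check trains a 56×56, C = 32,
depths (2, 2) dual model on 2 classes × 8 images for 30 epochs at learning
rate 10⁻³ (from-scratch training of a small model warrants a larger rate
than the fine-tuning default), monitoring training-set accuracy for
checkpoint selection.  The full 224×224 / C = 96 geometry is exercised in
forward mode, where stage shapes, the 1536-wide fused feature and the 22-way
simplex are asserted directly.

## Known limitations

- CPU-only, float32; no GPU or mixed precision.
- The full reference protocol (100 epochs on ~11.6k images) is supported by the
  code path but not practical on one CPU; the package is designed for
  correctness verification and small-scale experimentation.
- The fusion of edge information into the lower channel is interpreted as
  magnitude-only 3-channel replication; overlaying edges on the raw image is
  a plausible alternative reading, isolated behind `make_edge_input`.
- Only horizontal flips; vertical flips are off by default.
- No learning-rate schedules or hyper-parameter search.
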