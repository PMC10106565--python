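# Methods

## Model

`glsegnet` implements a U-shaped encoder–decoder for binary segmentation of
2-D medical images, built around three ideas: enriching the *shallow* skip
connections with multi-scale context, filtering the *deepest* features with a
vision-transformer (ViT) bottleneck, and gating every skip connection in the
decoder with a learned attention signal.

**Encoder.** A 7×7 stride-2 stem projects the 3-channel input to `c` channels
(64 by default), followed by one same-shape residual block; three further
residual blocks (each `Y = F(X, W) + X` with a 1×1 projection shortcut when
shapes change) halve the spatial size and double the channels, giving the
schedule `c, 2c, 4c, 8c` at scales 2, 4, 8, 16.

**Context-rich skip connections.**

* *MSC* (multi-scale convolution): four parallel 3×3 atrous convolutions with
  rates 1, 2, 4, 8 (padding = rate, so size-preserving), concatenated to `4c`
  channels and fused back to `c` by a 3×3 convolution.
* *MSP* (multi-scale pooling): non-overlapping max pooling at sizes 2, 4, 8,
  16, each branch reduced to a single channel by a 1×1 convolution and
  bilinearly upsampled back, giving a 4-channel summary.
* *Fusion*: stride-2 atrous convolutions (dilation 2, and 2→4 for the double
  hop) push the layer-1 features to scales 4 and 8 and the layer-2 features to
  scale 8; the branches are concatenated into the level-2 and level-3 skips.

With the defaults the level-1 skip is `concat(layer1, MSC, MSP)` =
64 + 64 + 4 = 132 channels at scale 2.

**ViT bottleneck.** The scale-16 map is split into P×P patches (P = 1 by
default, preserving every spatial position), linearly embedded to K
dimensions and given a learned, zero-initialized positional embedding (no
class token — this is dense prediction). Pre-norm transformer layers apply
`m' = MSA(LN(m)) + m; m = MLP(LN(m')) + m'` with multi-head scaled dot-product
attention `softmax(QKᵀ/√d_k)V` and a two-layer ReLU MLP. A final layer norm,
reshape to the spatial grid and 1×1 projection return a map of the encoder's
channel count. Presets: `base` = 12 layers / 768 hidden / 3072 MLP
(12 heads), `large` = 24 / 1024 / 4096 (16 heads). The positional embedding
is learned on the configured reference grid and bilinearly resized when the
network runs at a different input size.

**Decoder.** Each stage summarizes its skip bundle with a 3×3 convolution to
the stage width (256, 128, 64 at scales 8, 4, 2), upsamples the coarser
decoder feature 2× bilinearly, gates the summarized skip with
`AG(X, C) = σ(ψ(relu(WₓX + W_cC))) · C` (single-channel gate broadcast over
C's channels; intermediate width = half of C's channels), concatenates gated
skip and upsampled feature and fuses with a 3×3 convolution. A final 2×
upsample and a 7×7 convolution + sigmoid produce the probability mask. The
scale-2 stage is the last gated one; no skip exists at scale 1.

All 3×3/7×7 convolutions are followed by batch normalization and ReLU; 1×1
gating/projection convolutions are bare. Upsampling is bilinear with
pixel-center alignment. Weights are Kaiming-uniform, biases zero, all draws
from a seeded generator, so model construction is fully reproducible.

## Hybrid loss

`L = α·L₁ + β·L₂ + γ·L₃ + θ·L₄` with convex weights validated at
construction (`α+β+γ+θ = 1`, default 0.4 / 0.3 / 0.15 / 0.15 — region overlap
is the main objective, consistent with treating Dice as the primary loss).

* `L₁ = 1 − DSC` with smoothing ε = 1e-6 in numerator and denominator. The
  Dice *coefficient* is a similarity, so the minimized loss is its
  complement; two empty masks score a perfect 0.
* `L₂` = mean binary cross-entropy, prediction clamped to [1e-7, 1−1e-7].
* `L₃ = 1 − mean SSIM` over an 11×11 Gaussian window (σ = 1.5), stabilizers
  C₁ = (0.01)², C₂ = (0.03)² for unit dynamic range, valid windows only. The
  standard product form of the two SSIM factors is used.
* `L₄` = mean absolute difference of the 5-point Laplacians of prediction and
  truth (an edge-preservation penalty). Border pixels use replicate padding;
  an L2-norm variant is available via `edge_norm="l2"`.

All four terms are non-negative, vanish at `pred = gt`, and are
differentiable in the prediction; the test suite verifies the analytic
gradient against central finite differences at 1e-3 relative tolerance.

## Evaluation indices

`Dice` and `IoU` are computed on the prediction binarized at 0.5 (an adaptive
2×mean threshold is available); both-empty pairs score (1, 1). The weighted
F-measure (β = 1) and Structure-measure consume the continuous map, the
Enhanced-alignment measure the binarized one, each following its published
definition. One implementation detail is pinned down explicitly: the weighted
F-measure copies each background pixel's error from its *nearest* foreground
pixel, and on integer grids the nearest pixel can be tied; ties are broken
toward the lexicographically smallest (row, col) coordinate, and the test
oracle uses the same rule. The Structure-measure mixes object- and
region-aware terms with weight 0.5 each and uses `mean(gt)` inside the
object term, per its standard definition.

## Optimization

SGD with momentum 0.9, learning rate 0.01, weight decay 1e-4 (L2 added to the
gradient), batch size 4, constant learning rate, no augmentation. Training
logs the four loss terms per epoch, aborts on a non-finite term naming the
offender, evaluates the validation split each epoch and keeps best-by-MeanDice
and last checkpoints (flat `.npz` parameter maps plus a JSON config).

## Numerical engine

The network runs on a package-local reverse-mode autodiff engine over numpy
arrays (`glsegnet.autograd`): broadcasting arithmetic, matmul, conv2d with
stride/dilation (one GEMM per kernel tap), non-overlapping max pooling,
bilinear resize, padding, layer norm, softmax. Compute dtype is float32 by
default; float64 is used in the finite-difference tests. Every primitive is
validated against central differences in the test suite. Determinism: given
the same seed, parameters, batch order and BN statistics are bit-identical
across runs on the same machine.

## Synthetic data

The generator emulates "lesion on background" images: 1–3 superellipse blobs
with low-frequency radial perturbation (a crude analog of irregular tumor
margins), foreground offset +0.35 over a 0.30 background, boundary blur
(Gaussian σ = 1.5), a linear intensity gradient (±0.15 across the frame),
band-limited texture (σ = 3 smoothed noise, amplitude 0.06) and additive
Gaussian noise (σ = 0.03), clipped to [0, 1]; masks are exact by
construction. `(seed, index)` fully determine a sample via
`SeedSequence([seed, index])`, so any subset is independently reproducible.
It deliberately does **not** model modality physics (staining, dermoscopy
optics, MRI, X-ray), multi-scale clutter, or ambiguous boundaries — passing
the desk-scale learning test shows the architecture, loss and optimizer can
fit and generalize on controlled geometry, not that clinical-grade accuracy
is reached on real datasets.

## Problem sizes used by the tests and the acceptance script

The reduced `tiny` preset (stem 16 channels, 2 transformer layers, hidden 64,
decoder widths 64/32/16 — architecture-isomorphic to the full model) is
trained on 16 synthetic pairs at 64×64 for 50 epochs and evaluated on 8
held-out pairs; these sizes make a full train/evaluate cycle a ~2-minute CPU
run while leaving the full-width model exercised by forward-pass shape and
oracle tests at 256×256.

## Design choices where the architecture description was open

* Stem = one 7×7 stride-2 convolution (only "a convolution operation" is
  prescribed); channel schedule doubles per layer.
* MSC branches are single convolutions (branch depth unspecified); rates
  1/2/4/8.
* MSP has four branches (2/4/8/16) matching its four-channel output.
* Fusion downsampling uses stride-2 convolutions — padding alone cannot
  reduce spatial size; branch width 64 (= stem width).
* The gate's coarse input X is bilinearly upsampled to C's size before
  `WₓX + W_cC`, since the two operands must agree spatially.
* Patch size P = 1 on the 16×16 bottleneck map; heads 12/16 for base/large.
* "Iterations" in the training recipe are interpreted as epochs; batch size 4.
* Validation = the held-out test split; best checkpoint by MeanDice.

## Known limitations

* 2-D binary segmentation only; no multi-class head, deep supervision, or
  test-time augmentation.
* CPU-oriented numpy engine: full-width training at 256×256 is possible but
  slow; the package is designed for desk-scale experiments and testing.
* No pretrained transformer weights; the ViT trains from scratch, so very
  small datasets rely on the convolutional path for most of the fit.
* MSC enrichment of deep layers requires the feature map to exceed the
  largest dilated kernel (rate 8 ⇒ ≥ 17 px), so layer-3 enrichment needs
  ≥ 256 px inputs.
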