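# Methods and design notes

This note records what the package implements, the parameters and their
defaults, the numerical choices, and the design decisions that were open to
interpretation — including one reported figure that the implementation
deliberately does not reproduce.

## Model

MADR-Net is a U-Net-shaped encoder-decoder for 2-D segmentation.

**Encoder.** An initial 1×1 convolution lifts the input image (1 or 3
channels) to the first feature width, followed by six multi-dilated residual
blocks along the channel progression 32 → 64 → 128 → 256 → 512 → 1024 with
2×2 max pooling between the first five blocks and the next stage. Each block
runs four parallel branches at dilation rates 1, 3, 5, 11; a branch is two
stacked pre-activation units (batch norm → ReLU → dilated 3×3 convolution,
zero "same" padding). Branch outputs are summed element-wise in ascending
rate order (fixed order for bit-reproducibility) and added to a shortcut:
identity when channel counts match, a bias-free 1×1 projection otherwise.
There is no activation after the sum — the pre-activation form keeps the
block an exact identity when all branch weights are zero, which the tests
exploit. A dilated k×k kernel has an effective window of k + (k−1)(d−1)
pixels: 3, 7, 11, 23 for the four branch rates.

**Bottleneck and head.** Atrous spatial pyramid pooling with five parallel
branches: a 1×1 convolution, three dilated 3×3 convolutions (d = 6, 12, 18),
and a global-pooling branch (global average pool → 1×1 convolution →
broadcast back to H×W), each emitting out_channels/4 channels, concatenated
and fused by a 1×1 convolution. The bottleneck ASPP maps 1024 → 1024; a
second, narrow ASPP (width 32) sits between the head merge and the final 1×1
classifier.

**Decoder.** Five stages, each: 2×2 stride-2 transposed convolution, a
channel–spatial attention module applied to the resolution-matched encoder
feature, channel concatenation, and a multi-dilated residual block. The
final decoder feature is merged with the L1 feature (concatenation by
default, addition selectable) before the head ASPP. The output activation is
sigmoid for one class, per-pixel softmax otherwise.

**Layer registry.** The model carries an ordered registry of macro-layers —
one entry per named unit (conv-in, each residual block, each pool, the
bottleneck ASPP, each upsample/attention/concat/block decoder member, the
L1 merge, head ASPP, classifier, output activation). For the default depth
this yields 12 encoder entries (L1–L12), the bottleneck (L13), 23
decoder/head entries (L14–L36 plus the output activation L37), total 37, and
skip couplings (L14, L10), (L18, L8), (L22, L6), (L26, L4), (L30, L2) —
decoder stride +4, encoder stride −2. The convention generalizes to other
depths by the same stride rule. Reaching exactly these totals requires
counting six residual blocks in the encoder (one per entry of the channel
progression, the sixth producing the 1024-channel feature at bottleneck
resolution before the ASPP); a five-block reading leaves the encoder one
entry short of 12.

## The parameter-count discrepancy

The architecture is reported elsewhere as having 56 M trainable parameters.
That figure is arithmetically inconsistent with the architecture as
described: a single residual block mapping 512 → 1024 channels with four
branches of two 3×3 units holds 4·9·(512·1024 + 1024²) ≈ 56.6 M parameters
by itself. An enumeration of the plausible textual design space (one vs. two
convolutions per branch, full-width vs. quarter-width ASPP branches, pooling
branch on/off, concatenated vs. additive final merge) spans roughly 48–153 M
and never lands on 56 M. The faithful default build here has exactly
**126,448,440** trainable parameters, which `scripts/acceptance.py` reports
as 126 (nearest million). The corresponding acceptance assertion fails and
is left failing on purpose: the count is an exact integer property of the
architecture, and adjusting the architecture solely to hit the reported
number would misrepresent both.

## Losses

All losses accept probabilities p ∈ [0, 1] and binary/one-hot targets q of
shape (N, M, H, W) and return autodiff scalars.

* Binary cross-entropy: mean of −[q log p + (1−q) log(1−p)] over all
  elements, with p clipped to [1e-7, 1 − 1e-7].
* Categorical cross-entropy: −Σ q log p averaged over pixels (not classes),
  targets validated one-hot.
* Soft dice: 1 − (2Σpq + s)/(Σp + Σq + s), smoothing s = 1 by default so
  empty masks stay differentiable; s = 0 gives the exact 1 − DSC on hard
  masks (both-empty defined as 0 loss).
* Focal Tversky: Σ_m (1 − TI_m)^{1/γ} with
  TI = Σp₀q₀ / (Σp₀q₀ + α Σp₀q₁ + β Σp₁q₀), α = 0.7, β = 0.3, γ = 1.33
  (exponent 1/γ ≈ 0.752). With α = β = 0.5, γ = 1 it reduces to unsmoothed
  dice; a completely wrong hard prediction gives exactly M. A class absent
  from both prediction and target contributes 0. Note that for γ > 1 the
  focusing exponent is < 1, so the gradient of (1 − TI)^{1/γ} is unbounded
  as TI → 1 exactly; with probabilistic (sigmoid/softmax) predictions TI
  never reaches 1 and training is well-behaved, but the loss's gradient at a
  bit-exact perfect prediction is not finite. The cross-entropy clipping
  guarantee covers only the cross-entropy term.
* Hybrid: w_ce·CE + w_dice·Dice + w_ft·FT, default weights (1, 1, 1)
  (the combination weights are a free choice, exposed in `LossConfig`).

## Metrics

All metrics derive from per-image pixel confusion counts: DSC =
2TP/(2TP+FP+FN), IoU, accuracy, precision, recall, with DSC =
2·IoU/(1+IoU) as an identity. Convention for empty masks: overlap metrics
are 1 when both masks are empty, 0 when exactly one is. Multiclass scoring
is one-vs-rest per class with macro (default; background inclusion
configurable) or micro (pooled counts) aggregation. Sigmoid outputs are
binarized at a configurable threshold, default 0.5. Reports aggregate by the
mean of per-image metrics (pooled-count aggregation available via micro).

## Synthetic data

The generator produces fixtures that mimic the statistical shape of common
medical segmentation tasks without using any real dataset:

* **binary** — 1–3 smooth random-ellipse blobs with low-frequency boundary
  perturbations on a Gaussian-filtered background texture, plus additive
  noise; rejection sampling keeps the foreground fraction inside a band
  (2–40 % by default) to exercise class imbalance.
* **multiclass3** — an inner ellipse (label 1) strictly nested in an
  elliptical ring (label 2) with a disjoint adjacent region below (label 3),
  a cardiac-like geometry.

Generation is fully deterministic (one integer-seeded PCG64 stream per
call): the same spec yields byte-identical arrays. Scope limits: these are
statistical stand-ins, not simulations — no speckle physics, no instrument
noise models, no patient-level structure (the 80/10/10 split is index-level
for the same reason). Benchmark scores on real datasets are therefore out of
scope here; the test suite instead verifies mechanism (capacity, gradients,
determinism, metric/loss identities). Preprocessing is min-max normalization
to [0, 1] with bilinear resizing for images and nearest-neighbor for masks;
augmentation is flips, 90° rotations, and small intensity jitter, applied
identically to image and mask.

## Training protocol

Adam (lr 1e-3), batch size 16, up to 500 epochs, 80/10/10
train/validation/test split (⌊0.8n⌋/⌊0.1n⌋/remainder), reduce-on-plateau
learning-rate decay (factor 0.5, patience 20, monitoring validation DSC —
the decay schedule itself was an open choice). The best-validation-DSC
checkpoint is retained; per-epoch loss components and validation DSC go to a
CSV log. Non-finite loss aborts with a diagnostic. Fewer than 10 samples
switches to the overfitting regime (train = validation = all), used by the
capacity check: a tiny configuration (channels 4…128, 64×64 input) reaches
mean DSC 1.0 on 8 synthetic images within 300 steps.

## Numerical choices

The autodiff engine is single precision by design: every tensor is float32,
so mixed-dtype arithmetic can never silently promote the graph to float64
(which would double GEMM cost and break dtype invariants). Convolutions are
evaluated as one im2col gather plus a BLAS matmul; the transposed
convolution and its gradients are likewise single matmuls. The sigmoid is
computed in the overflow-free form (exponentials only of non-positive
arguments), and the sigmoid head output is clipped to [1e-7, 1 − 1e-7] so
the probability contract "strictly inside (0, 1)" survives float32
saturation on large logits. Batch-norm uses batch statistics in training and
running moments (momentum 0.1) in eval mode. Weight initialization is
He-style from an explicitly passed generator, so a model built twice from
the same seed is bit-identical.

## Open design choices (and how they were resolved)

* **Layer-counting convention** — six encoder residual blocks; see above.
* **ASPP branch width** — out_channels/4 per branch ("four equal
  partitions" reading); the pooling branch uses global *average* pooling by
  default with max selectable (`aspp_pool_mode`).
* **Attention MLP nonlinearity** — the hidden activation defaults to a
  leaky rectifier rather than ReLU: at the tiny hidden widths produced by
  C/r (often 1 in small configs) a dead ReLU can zero the whole gate's
  gradient at initialization; leaky units keep every parameter reachable.
  Plain ReLU and no activation are selectable (`mlp_activation`).
* **Attention hidden width** — max(C/r, 1) so configurations with C < r
  remain valid; r = 16 by default.
* **Input size** — 128 default (divisible by 2⁵); 112 is not.
* **Head merge with L1** — channel concatenation by default, addition
  selectable (`l1_merge`).
* **Head ASPP width** — 32 channels (first-stage width) before the
  classifier.
* **Hybrid weights, binarization threshold, dice smoothing** — (1, 1, 1),
  0.5, and s = 1 respectively, all configurable.
* **Block dilation rates** — (1, 3, 5, 11) default, configurable.
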