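# madrnet

A self-contained implementation of MADR-Net, a multi-level attention dilated
residual neural network for 2-D medical-image segmentation, together with its
hybrid loss, evaluation metrics, a seeded synthetic data generator, and a
train/eval/predict command-line workflow. The whole stack runs on a small
NumPy reverse-mode autodiff engine — no deep-learning framework is required.

## The problem

Semantic segmentation of biomedical images (lesions in dermoscopy, cardiac
structures in ultrasound, mitochondria in electron microscopy) must label
every pixel under heavy class imbalance, blurred boundaries, and structures
that appear at several spatial scales at once. MADR-Net addresses this with a
U-Net-shaped encoder-decoder whose building blocks widen the receptive field
and re-weight features without adding depth:

* **Multi-dilated residual blocks** — four parallel branches of stacked
  pre-activation units (batch norm → ReLU → 3×3 convolution) at dilation
  rates *d* = 1, 3, 5, 11, summed and added to an identity/1×1-projection
  shortcut. A dilated kernel sees an effective window of
  *k + (k−1)(d−1)* pixels (11×11 at *d* = 5) at the parameter cost of 3×3.
* **Atrous spatial pyramid pooling (ASPP)** at the bottleneck and before the
  classifier: parallel 1×1, dilated 3×3 (*d* = 6, 12, 18), and
  global-pooling branches, concatenated and fused by a 1×1 convolution.
* **Channel–spatial attention (CSAM)** on every skip connection: a
  per-channel sigmoid gate `W_C(F) = σ(W₁(W₀(avg)) + W₁(W₀(max)))` followed
  by a per-pixel gate from a 7×7 convolution over the channel-pooled
  mean/max maps, applied as `F₂ = W_S(F₁) ⊗ F₁`, `F₁ = W_C(F) ⊗ F`.

The encoder follows the channel progression 32 → 64 → 128 → 256 → 512 → 1024
with 2×2 max pooling; the decoder mirrors it with 2×2 transposed-convolution
upsampling. The default model maintains a 37-entry layer registry (12 encoder
entries, 1 bottleneck, 23 decoder/head entries, 1 output activation) with
skip couplings (L14, L10), (L18, L8), (L22, L6), (L26, L4), (L30, L2).

Training minimizes a hybrid loss: cross-entropy + soft dice + focal Tversky
(α = 0.7, β = 0.3, γ = 1.33, exponent 1/γ) with equal weights, optimized by
Adam (lr 1e-3, batch 16, ≤500 epochs, reduce-on-plateau) on an 80/10/10
split. Metrics (dice, Jaccard, accuracy, precision, recall) all derive from
per-image pixel confusion counts.

## Worked example

```bash
# 16 seeded synthetic blob images at 32x32
madrnet gen-data --out data --n 16 --input-size 32 --seed 0

cat > cfg.yaml <<'EOF'
model:
  in_channels: 1
  num_classes: 1
  input_size: 32
  channel_progression: [4, 8, 16, 32]
epochs: 40
batch_size: 8
seed: 0
EOF

madrnet train --config cfg.yaml --data data --out run --seed 0
madrnet eval  --checkpoint run/best --data data --out report
madrnet predict --checkpoint run/best --out pred data/img_0000.png
```

On one CPU core this trains in about 15 seconds and prints:

```
epoch   39  loss 0.0157  val DSC 0.8498
best val DSC 0.8498 (epoch 39); checkpoints in run
```

and evaluation over all 16 images reports:

```
{
 "dsc": 0.9808069788049067,
 "iou": 0.9648862469723065,
 "accuracy": 0.995361328125,
 "precision": 0.9914124712802862,
 "recall": 0.9725987544878708
}
```

(The evaluation set here includes the training images; the val DSC above is
the held-out score from the 80/10/10 split.)

The same workflow is available as a library:

```python
import numpy as np
from madrnet import (ModelConfig, TrainConfig, SyntheticSpec,
                     build_model, generate, train)

spec = SyntheticSpec(n_images=16, image_size=32, seed=0)
images, masks = generate(spec)
cfg = TrainConfig(model=ModelConfig(in_channels=1, num_classes=1,
                                    input_size=32,
                                    channel_progression=(4, 8, 16, 32)),
                  epochs=40, batch_size=8, seed=0)
result = train(cfg, images, masks, "run")
print(result["best_val_dsc"])
```

## Layout

```
src/madrnet/
  autograd.py   reverse-mode autodiff engine (float32, im2col convolutions)
  nn.py         Module/Parameter layers: conv, transposed conv, batch norm
  optim.py      Adam + reduce-on-plateau schedule
  blocks.py     conv unit, multi-dilated residual block, ASPP, CSAM
  model.py      full network assembly + L1..L37 layer registry
  losses.py     BCE/CCE, soft dice, focal Tversky, hybrid
  metrics.py    confusion-count metrics, multiclass report
  synthetic.py  seeded binary / 3-class fixture generator, augment, split
  train.py      training loop, checkpointing, evaluation reports
  cli.py        madrnet gen-data | train | eval | predict
docs/methods.md   design notes, assumptions, and open choices
scripts/acceptance.py   quantitative targets as JSON
tests/            unit, property, and acceptance tests
```
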