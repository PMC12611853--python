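# noduleseg

Semantic segmentation of lung nodules in CT slices: a CT preprocessing
pipeline, three encoder–decoder segmentation networks, the BCE–Dice training
objective and overlap-based evaluation — all runnable end to end on
synthetic thorax phantoms, with no external data or GPU.

Lung nodules are small, low-contrast and easily confused with vessels and
the pleural wall, which makes their pixel-accurate delineation one of the
standing problems of thoracic CT analysis. This package implements three
multi-scale architectures for that task and the infrastructure around them:

* **Multi-scale UNet** — a UNet whose stages extract features with parallel
  3×3 and 7×7 convolutions, fused by a 1×1 convolution, so each stage sees
  both fine boundary detail and broad anatomical context.
* **ACB-UNet** — a five-level UNet whose blocks are *asymmetric convolution
  blocks* (the sum of 3×3, 1×3 and 3×1 branches, emphasizing the kernel's
  central cross), with multi-scale skip fusion across all encoder/decoder
  levels and CBAM-style channel attention re-weighting the fused features.
* **FPN with linear attention** — a ResNet-34 bottom-up pathway, an FPN
  top-down pathway with lateral connections, and an aggregation module that
  concatenates the pyramid maps P2–P5 (256 channels), refines them with
  single-head *linear attention*, and adds them back residually.

The linear attention mechanism replaces softmax weights
`exp(qᵀk)` with the first-order Taylor expansion `1 + q̂ᵀk̂` over
L2-normalized queries and keys, so that

    out_x = ( Σ_y v_y + q̂_xᵀ Σ_y k̂_y v_yᵀ ) / ( M + q̂_xᵀ Σ_y k̂_y )

where the key/value summaries are computed once and reused for every query —
O(M) time and memory in the number of spatial positions M, against O(M²) for
softmax attention. Normalization guarantees `q̂ᵀk̂ ≥ −1`, so the implicit
attention weights are non-negative and sum to one.

Because no deep-learning framework is assumed, the networks run on a compact
numpy autograd engine included in the package (`noduleseg.autograd`):
define-by-run reverse-mode differentiation with conv2d / transposed-conv /
pooling / bilinear primitives, batch normalization and Adam. Everything is
float32 and deterministic under a seed.

## Worked example

```python
from noduleseg import ModelConfig, TrainConfig, build_model
from noduleseg.activations import ActivationSpec
from noduleseg.synthetic import generate_phantom_dataset, scaled_config
from noduleseg.train_eval import evaluate_model, train_model

parts = generate_phantom_dataset(20, scaled_config(64, seed=0))
model = build_model(ModelConfig(architecture="fpn_la", seed=0,
                                activation=ActivationSpec("gelu")))
model, history = train_model(model, parts["train"], parts["val"],
                             TrainConfig(epochs=3, batch_size=8,
                                         learning_rate=1e-4, seed=0))
print(history[0].train_loss, history[-1].train_loss)
report = evaluate_model(model, parts["test"])
print(report.dsc, report.iou)
```

On this tiny three-epoch run the mean training loss falls (0.8246 → 0.8006)
while the held-out Dice similarity coefficient (DSC, `2|G∩P|/(|G|+|P|)`)
is still near zero (0.0257) — three epochs only begin to move 22 million
parameters. The longer scaled-down runs in the test suite and acceptance
script (15 epochs, 128 phantoms, learning rate 1e-5) reach a held-out DSC
of ≈0.16 for the FPN versus ≈0.02 for its untrained twin. The `examples/` directory holds one short narrative script per
capability (phantom generation, lung extraction, linear attention, training);
each prints the numbers it computes and what they mean.

A thin command line mirrors the library:

```
noduleseg generate --n 8 --seed 1 --out phantoms/
noduleseg train --arch fpn_la --n-phantoms 64 --epochs 15 --seed 1 --out run/
noduleseg evaluate --checkpoint run/model.npz --out report.json
noduleseg predict phantoms/phantom_0000.png --checkpoint run/model.npz --out mask.png
```

## What real CT adds that phantoms do not

The phantom generator emulates the geometry the pipeline needs (air-dark
lungs, brighter nodules, additive noise) but not scanner physics, vessels,
or ground-glass texture; results on phantoms demonstrate that the
implementation learns and evaluates correctly, not clinical performance.
For real data the `io` module reads DICOM (with Hounsfield rescaling),
NIfTI and PNG slices, and parses LIDC-style XML or simplified JSON
multi-reader contour annotations with ≥3 mm nodule filtering and per-pixel
consensus voting. See `docs/methods.md` for the full model and parameter
documentation.
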