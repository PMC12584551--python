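# dcceunet

Lesion segmentation for B-mode ultrasound with an attention-augmented
U-Net (DCCE-UNet), a seeded speckle-phantom simulator, and a complexity
audit — implemented end to end on a self-contained NumPy autodiff engine,
with no deep-learning framework dependency.

Ultrasound segmentation is hard for modality-specific reasons: granular
multiplicative speckle, low lesion/tissue contrast, blurred boundaries and
irregular lesion shapes. DCCE-UNet extends the classical U-Net
encoder–decoder with three modules aimed at exactly those failure modes:

* **MASG** (multi-source attention-guided semantic generation), at the
  bottleneck: embeds the bottleneck feature together with a shallow and a
  deep reference feature, builds a contrastive-difference attention map
  `A = σ(Conv(Conv(concat(F′_in − F′_fg, F′_in − F′_bg))))`, gates
  residually `F_att = F′_in + A ⊙ F′_in`, aggregates context with four
  parallel dilated 3×3 convolutions (rates {1, 6, 12, 18}), and emits an
  auxiliary deep-supervision prediction.
* **BDA** (bidirectional difference-aware attention), on every skip
  connection: models cross-stage differences
  `F_sub = F_enc − SAVA(F_dec)`, re-weights residually
  `F_mod = F_enc + σ(BN(Conv(F_sub))) ⊙ F_enc` (and symmetrically for the
  decoder pathway), then differences the two pathways through a final
  spatial-variance-aware attention (SAVA) module. Identical inputs give an
  exactly zero output — the signature of a difference detector.
* **CAG** (context-aware guidance), after every decoder stage: depthwise
  1×k and k×1 strip convolutions on a pooled context grid collect
  row/column long-range context; `A_cag = σ(Conv(F_h + F_v))` gates the
  decoder feature residually, `F_cag = F_dec + A_cag ⊙ F_dec`.

Training minimises `L_total = L_ce + L_dice + λ_aux · L_aux` (cross-entropy
+ batch-pooled soft Dice + weighted auxiliary cross-entropy) with SGD
(momentum 0.9, weight decay 5e-5), cosine-annealed learning rate from
0.01, 8:1:1 seeded splits, and best-validation-Dice checkpointing.
Evaluation reports Dice, IoU, pixel accuracy, recall, specificity and
precision, scored at native mask resolution.

Because clinical datasets (BUSI, TN3K) cannot be bundled, the package
includes a phantom generator that emulates the difficulty factors —
hypoechoic lesions with Fourier-perturbed elliptical contours, Gaussian
boundary blur, unit-mean Gamma speckle, acoustic shadowing, additive noise
— so every component is testable at desk scale from a seed.

## Worked example

Generate 60 phantoms, train a small full model for 6 epochs, evaluate on
the held-out split:

```bash
dcceunet phantom --n 60 --size 64 --seed 7 --out demo/data
```

```python
import json
from dcceunet import (ModelConfig, TrainConfig, train, evaluate,
                      load_split, load_checkpoint)

mc = ModelConfig.tiny()                      # base width 16, all modules on
tc = TrainConfig(epochs=6, batch_size=8, resize=(64, 64), seed=0)
best, hist = train(mc, tc, "demo/data", out_dir="demo/run")
for h in hist:
    print(f"epoch {h['epoch']}  lr {h['lr']:.4f}  "
          f"loss {h['loss_total']:.3f}  val dice {h['val_dice']:.3f}")

model, meta = load_checkpoint("demo/run/best.npz")
_, _, test = load_split("demo/data", tc.split_ratios, tc.seed)
rep = evaluate(model, test, tc.resize)
print(json.dumps({k: round(v, 1) for k, v in rep.to_percent_dict().items()}))
```

Output:

```
epoch 0  lr 0.0100  loss 1.651  val dice 0.000
epoch 1  lr 0.0093  loss 1.184  val dice 0.026
epoch 2  lr 0.0075  loss 0.732  val dice 0.541
epoch 3  lr 0.0050  loss 0.452  val dice 0.550
epoch 4  lr 0.0025  loss 0.343  val dice 0.717
epoch 5  lr 0.0007  loss 0.292  val dice 0.796
{"dice": 77.7, "iou": 64.3, "accuracy": 96.1, "recall": 80.5, "specificity": 97.3, "precision": 82.0}
```

The learning rate follows the cosine schedule from 0.01 toward 0; the loss
falls monotonically; the checkpoint holds the epoch with the best
validation Dice (0.796 here — six epochs on 48 training phantoms; the
bundled acceptance check trains longer on more phantoms and reaches ≈ 0.90).
The test row says: on held-out phantoms, predicted masks overlap ground
truth with 77.7 % Dice (64.3 % IoU) while classifying 96.1 % of pixels
correctly; recall/precision ≈ 80 % mean misses and false alarms are
balanced.

The complexity audit reproduces the published parameter/MAC ladder of the
four ablation variants (U-Net → +BDA → +BDA+CAG → full) at 224×224:

```bash
$ dcceunet audit --variant unet --input-size 224 --expect-params 4.30 --expect-gmacs 7.76
variant=unet input_size=224 params_millions=4.318 gmacs=7.788
```

`ModelConfig`'s defaults are calibrated so each variant lands on the
published budget (the scripted search lives in
`scripts/calibrate_budget.py`); the one exception — the full model's MAC
total — is discussed in `docs/methods.md`. A real-data run uses the same
commands with a BUSI/TN3K-style folder of PNG images and masks (either
`images/` + `masks/` or `*_mask.png` companions).

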