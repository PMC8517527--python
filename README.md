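# mfuseg

Liver/tumor CT segmentation toolkit: Hounsfield-unit preprocessing, a
multiple-filter U-net (MFU-net), seeded training with
best-validation-Dice checkpointing, and a six-metric volumetric evaluation
suite — exercisable end to end on built-in synthetic phantom volumes.

## Who this is for

Researchers building or evaluating slice-wise semantic segmentation of
abdominal CT (background / liver / tumor) who want a fully reproducible,
dependency-light reference pipeline.  Everything runs on the CPU and on
synthetic data; real NIfTI volumes (e.g. LiTS-style exports) plug in
through the same I/O layer but are never required.

## The method

**Preprocessing** (per slice): Hounsfield filtering
`H(I) = slope·I + Intercept` with `slope = 0.00390625` and
`Intercept = 0.1·min(I)` if `min(I) ≤ 0` else `−min(I)`, then min-max
rescaling to [0, 255], then mean-driven standardization
`S(I) = (α·I + β) + (I/255)^γ·255` where the slice mean μ selects
`α ∈ [1,2]`, `β ∈ [1,1.2]`, `γ ∈ [1.5,2]` — darker slices get stronger
adjustment.

**Network**: a U-shaped encoder-decoder.  The encoder is ResNet18-style
(7×7 stem, max-pool, four stages of two residual blocks).  The decoder is
ten *MF blocks* in five upsampling levels; an MF block runs parallel 1×1,
3×3 and 5×5 convolutions, concatenates them along channels, and applies
ReLU, capturing local and wider context simultaneously.  Skip connections
carry encoder features to the matching decoder level.  A 1×1 head yields
three class scores; prediction is the per-pixel softmax argmax (per-class
0.5-thresholded masks are also exposed).

**Training**: Adagrad (lr 1e-3 full scale), batch 16, random 80/20
train/validation split, fixed epoch budget, checkpoint = weights of the
epoch with the best validation Dice.  Loss: cross-entropy + soft Dice.
The network and training loop run on the package's own NumPy autodiff
engine (`mfuseg.nn`) — no deep-learning framework needed; all gradients
are finite-difference verified in the tests.

**Evaluation**: for each structure (liver = labels {1,2} merged, tumor =
label 2), six metrics of prediction B against reference A:

| metric | definition | units |
|---|---|---|
| ASSD | mean of pooled bidirectional surface distances | mm |
| MSSD | max of pooled distances (symmetric Hausdorff) | mm |
| RMSD | root mean square of pooled distances | mm |
| RVD  | (\|B\|−\|A\|)/\|A\|, signed | — |
| VOE  | 100·(1 − \|A∩B\|/\|A∪B\|) | % |
| Dice | 2\|A∩B\|/(\|A\|+\|B\|) | fraction |

Surface voxels are foreground voxels with a background 6-neighbour;
distances are Euclidean in mm under anisotropic voxel spacing.

## Worked example

```python
import numpy as np
from mfuseg import (PhantomConfig, NetworkSpec, TrainConfig, build_mfunet,
                    train, generate_slice_dataset, generate_phantom,
                    predict_volume, evaluate_volume)
from mfuseg.preprocessing import preprocess_slice, preprocess_volume

pairs = [(preprocess_slice(im), lab)
         for im, lab in generate_slice_dataset(200, PhantomConfig(), seed=7)]
net = build_mfunet(NetworkSpec(base_width=6), seed=7)
best, history = train(net, pairs, TrainConfig(learning_rate=1e-2, epochs=10, seed=7))
print(f"baseline {history.baseline_dice:.3f} -> "
      f"final liver dice {history.rows[-1]['dice_liver']:.3f}")

vol, gt = generate_phantom(PhantomConfig(seed=12345))
report = evaluate_volume(predict_volume(net, preprocess_volume(vol)), gt)
print(f"held-out liver dice {report.liver.dice:.3f}, ASSD {report.liver.assd:.2f} mm")
```

prints (≈60 s on one CPU):

```
baseline 0.145 -> final liver dice 0.934
held-out liver dice 0.985, ASSD 0.08 mm
```

The untrained network scores a validation Dice of 0.145; ten epochs later
the liver is segmented at 0.93 on validation slices and 0.99 on a phantom
volume it has never seen, with a mean surface error under a tenth of a
millimetre.  Tumors — small, low-contrast, randomly placed — need a larger
width and more data to generalise (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
mfuseg phantom --n 20 --out data/ --seed 7
cat > cfg.yaml <<'YAML'
train: {epochs: 10, learning_rate: 0.01, seed: 7}
model: {base_width: 6}
YAML
mfuseg train --data data/ --out run/ --config cfg.yaml
mfuseg predict --model run/best.npz --in data/img_0000.nii.gz --out pred.nii.gz
mfuseg evaluate --pred pred.nii.gz --gt data/lbl_0000.nii.gz --out report.json
```

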