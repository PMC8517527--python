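# Methods

## Problem setting

`mfuseg` implements an end-to-end pipeline for simultaneous liver and tumor
semantic segmentation of abdominal CT: each axial slice of a volume is
preprocessed, segmented into three classes (background, liver, tumor) by a
convolutional encoder-decoder network, and the per-slice label maps are
reassembled into a volume that is scored against a reference with six
volumetric metrics in physical units.  Every stage runs on seeded synthetic
phantoms, so the whole pipeline is testable without any external imaging
data.

## Preprocessing

Per slice, in order:

1. **Hounsfield filtering.**  `H(I) = s·I + c` with slope `s = 0.00390625`
   (= 1/256) and intercept `c = 0.1·min(I)` if `min(I) ≤ 0`, else
   `c = −min(I)`.  The branch on the minimum anchors raw HU slices (air
   ≈ −1000) and already-offset exports to a common near-zero band.
2. **Rescaling** of the filtered slice to the working range [0, 255] by
   min-max (a constant slice maps to all zeros).  The standardization's
   gamma term `(I/255)^γ` presupposes this domain; the filter output is
   otherwise numerically near zero.
3. **Parameter selection.**  The slice mean μ (optionally over nonzero
   pixels only, since 0 marks background after rescaling) drives the
   strength of the adjustment through
   `u = clip(1 − μ/μ_ref, 0, 1)`, `α = 1 + u ∈ [1,2]`,
   `β = 1 + 0.2u ∈ [1,1.2]`, `γ = 1.5 + 0.5u ∈ [1.5,2]`, with
   `μ_ref = 128` (midpoint of the working scale, configurable).  Dark
   slices receive the strongest brightening/contrast boost; the mapping is
   monotone and always lands inside the stated intervals.  Only the use of
   the mean as the threshold is prescribed by the method; the linear
   interpolation is this package's concrete choice.
4. **Standardization.**  `S(I) = (α·I + β) + (I/255)^γ·255`, an affine
   scale/shift plus a gamma contrast term.  S is strictly increasing in the
   pixel value for all in-range parameters, so intensity ordering is
   preserved.

The stages compose sequentially (S is applied to the rescaled filter
output).  An additive combination `H + S` is available (`mode="sum"`,
CLI `--eq1-sum`) because the combination rule admits either reading; the
composition is the default since the filtered image is depicted as the
input of the standardization stage.

## The MF block and the MFU-net

The **multiple-filter (MF) block** runs three convolutions in parallel on
the same input — kernel sizes 1×1, 3×3, 5×5 with paddings 0/1/2, stride
1 — concatenates the three outputs along channels and applies ReLU.  The
original block description also mentions a down-sampling factor of 2 in the
larger branches, which is irreconcilable with concatenation of equal-sized
maps; all branches therefore run at full resolution and all resolution
changes live between decoder levels.  Batch normalization after each branch
convolution is on by default (toggleable, `batch_norm=False` gives the bare
conv+concat+ReLU block).

The **MFU-net** is U-shaped:

* Encoder: ResNet18 topology — 7×7 stem (stride 2), 3×3 max-pool
  (stride 2), four stages of two basic residual blocks with widths
  (w, 2w, 4w, 8w) where `w = base_width`.  One input channel, no
  pretraining.
* Decoder: exactly ten MF blocks arranged as five levels of two blocks.
  Each level: 2× nearest-neighbour upsampling → optional skip
  concatenation → two MF blocks.  Level output widths are
  (4w, 2w, w, w, w); each width splits across the (1×1, 3×3, 5×5) branches
  as evenly as possible with the remainder to the 3×3 branch.
* Skips: default `"unet"` wiring concatenates each encoder stage into the
  matching decoder level (stage3→level1, stage2→level2, stage1→level3,
  stem→level4).  The literal single-skip reading is available as
  `skips="single"` (stem skip only).
* Head: 1×1 convolution to 3 class scores.  Inputs must be divisible by 32
  (the encoder's downsampling factor).

Prediction applies a per-pixel softmax; the label map is the argmax class,
and per-class binary masks at probability ≥ 0.5 are exposed separately
(`threshold_masks`).  When the argmax class has probability below 0.5 the
argmax label is still reported; the thresholded masks let a caller apply
the stricter rule.

### The NumPy network engine

The package ships its own small reverse-mode autodiff engine
(`mfuseg.nn`): a `Var` graph over NumPy arrays with the 2-D ops the network
needs (convolution as a sum over kernel offsets through BLAS, batch norm,
ReLU, overlapping max-pool, nearest upsampling, concatenation) plus the
softmax cross-entropy / soft-Dice losses and Adagrad.  Everything is
float64 and single-threaded-deterministic; every analytic gradient is
checked against central finite differences in the test suite.  Weight
initialisation is He-normal from a single `numpy.random.Generator`, so a
build is bit-reproducible from its seed.

## Training

Defaults follow the full-scale recipe: Adagrad with learning rate 1e-3,
50 epochs, batch size 16, random 80/20 train/validation split, and the
checkpoint is the weights of the epoch with the highest validation Dice
(earliest epoch on ties).  Validation Dice is the unweighted mean of liver
and tumor Dice over validation slices; a slice where a structure is absent
from both prediction and reference scores 1 for that structure.  The liver
structure merges labels {1, 2} everywhere (a tumor voxel lies inside the
liver).

The loss is selectable (`ce`, `dice`, `ce+dice`; default `ce+dice`): pixel
cross-entropy plus one minus the mean soft Dice of the two foreground
classes, with global batch sums and ε = 1e-7 in numerator and denominator
so an absent class contributes no penalty at the one-hot limit.  The loss
is unspecified in the original method description; a compound CE + Dice
objective is the standard choice for class-imbalanced segmentation.

The split here is per-slice; when volumes carry case identifiers the CLI
groups slices per case to avoid leakage between train and validation.
Training runs on all slices by default (background-only planes teach the
network to stay silent outside the liver); `--liver-slices-only` restricts
to liver-bearing planes.

### Desk-scale preset

CPU-scale runs (tests, the acceptance script) use a width-reduced network,
`base_width = 6` (the full-scale network uses 64), and learning rate 1e-2.
At width 6 Adagrad's accumulator makes 1e-3 far too slow to converge in
tens of epochs; 1e-2 reaches validation liver Dice > 0.93 within 10 epochs
on 200 phantom slices.  These two knobs are the package's scaled-down
preset; everything else (optimizer, batch size, split, checkpoint rule)
matches the full-scale defaults.

## Evaluation metrics

Let A be the reference mask and B the predicted mask of one structure.

* A **surface voxel** is a foreground voxel with at least one background
  6-neighbour; the grid border counts as background, so structures touching
  the volume edge contribute edge voxels.
* **Surface distances** pool `d(s_A, S(B))` over all surface voxels of A
  with `d(s_B, S(A))` over all of B; distances are Euclidean between voxel
  centres with anisotropic spacing, computed exactly via a spacing-aware
  Euclidean distance transform (`scipy.ndimage.distance_transform_edt`).
  The test suite verifies the transform path against an all-pairs brute
  force to 1e-9 mm.
* **ASSD** = mean, **MSSD** = maximum (symmetric Hausdorff), **RMSD** =
  root mean square of the pooled distances (mm).  The power-mean inequality
  guarantees ASSD ≤ RMSD ≤ MSSD.
* **RVD** = (|B| − |A|)/|A|, reported signed by default so over- vs
  under-segmentation is visible (an absolute variant is available).
* **VOE** = 100·(1 − |A∩B|/|A∪B|) percent; **Dice** = 2|A∩B|/(|A|+|B|),
  related by Dice = 2J/(1+J) with J the Jaccard index.

Degenerate inputs: Dice(∅,∅) = 1 and VOE(∅,∅) = 0 (perfect agreement on an
absent structure); surface metrics and RVD with an empty reference are
undefined and reported as missing rather than 0 or ∞, so absent structures
neither reward nor punish the distance statistics.

## Phantom generator

A phantom is a (16, 64, 64) voxel grid at (2.5, 0.7, 0.7) mm spacing — the
anisotropy keeps the distance metrics honest — containing one ellipsoidal
liver (default radii (6, 22, 22) voxels, jittered per phantom in centre and
radii) and 1–3 spherical tumors placed strictly inside the liver (a
one-voxel dilation of each tumor must stay within the liver support;
placement is rejection-sampled inside the per-axis feasible region and
fails loudly after bounded retries).  Intensities are Hounsfield-like:
background −100, liver 60, tumors ±40 relative to liver (hypo- or
hyper-intense, 50/50 by default), plus additive Gaussian noise (σ = 10).
All draws come from one `numpy.random.Generator` per phantom, so output is
byte-identical under a fixed config and seed; dataset generation derives
per-item seeds from a master seed and records them in a manifest.

What the phantoms do **not** emulate: CT physics (beam hardening, partial
volume, streak artefacts), other organs, irregular tumor shapes,
inter-slice correlation of noise.  Passing tests on phantoms therefore
demonstrate that the pipeline's machinery (preprocessing arithmetic,
network mechanics, training loop, metric geometry) is correct and that the
network can learn simple contrast-defined anatomy — they say nothing about
segmentation quality on clinical CT.

## Numerical and design notes

* Internal grids are (z, y, x) with spacing in the same order; NIfTI I/O
  transposes at the boundary and passes the affine through untouched.  No
  resampling or reorientation anywhere.
* Geometry is voxel-index based; spacing enters only in the surface-distance
  metrics.
* Batch norm: biased variance for normalisation, unbiased in the running
  buffers, momentum 0.1, ε = 1e-5; eval mode uses the running buffers.
* Ties in `argmax` resolve to the lowest class index (NumPy convention);
  ties in the best-epoch selection resolve to the earliest epoch.
* The 80/20 split rounds the validation size to the nearest item and clamps
  so both parts are non-empty.
* Training determinism: data shuffling uses a dedicated generator seeded
  from the training seed; two runs with identical seed, data and thread
  count produce bit-identical histories.

## Known limitations

* Pure-NumPy training is CPU-bound; the full-width 512×512 configuration is
  out of desk-scale reach by design.  The architecture code is
  width-agnostic, so the full model is expressible, just slow to train.
* Tumor generalisation at the desk scale is weak: with a width-6 network
  and a few hundred phantom slices, held-out-volume tumor Dice is low even
  when validation-slice tumor Dice is moderate.  Liver segmentation
  generalises well (held-out Dice ≈ 0.99).  This mirrors the class
  imbalance and capacity limits of the reduced setting, not a defect of the
  loss or metrics.
* The per-slice validation Dice averages whole-slice scores, so a handful
  of stray foreground pixels on a background-only slice costs that slice
  its full point; volume-level metrics are the more stable summary.
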