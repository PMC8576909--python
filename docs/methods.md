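# Methods

## Overview

`lungnodule` implements a two-stage lung-nodule analysis pipeline for 3-D
chest CT: a 3-D residual U-Net segments nodule voxels from preprocessed CT
volumes, and a modified 3-D ResNet50 classifies cropped nodule regions as
benign or malignant. Because clinical CT collections cannot ship with a
software package, every stage is exercised end-to-end on synthetic phantoms
with exact ground truth; this note records the models, the parameters that
matter, and what the synthetic experiments do and do not demonstrate.

## Preprocessing

CT intensities are Hounsfield units (HU): air ≈ −1000, lung parenchyma
≈ −850 to −700, soft tissue ≈ +40. All arrays are indexed (axial, coronal,
sagittal), 0-based, with half-open crop windows.

* **Lung window.** Intensities are clipped to [−1000, 400] HU and mapped
  affinely to [0, 1]. This range covers lung tissue and soft-tissue lesions
  and is the network input scale.
* **Parenchyma extraction.** The lungs appear as low-attenuation regions
  enclosed by the high-attenuation chest wall. The mask is built by
  (1) thresholding at −320 HU (between parenchyma and soft tissue; the cut
  is not critical because the two modes are ~900 HU apart), (2) deleting
  low-density components 6-connected to any volume face (ambient air) and
  components mostly outside the filled body region (air pockets under the
  bed), (3) keeping the largest one or two remaining components (the second
  is kept when it is at least 10 % of the first, so separate left/right
  lungs survive but small artifacts do not), (4) filling holes slicewise
  (vessels and nodules are internal holes and belong to the parenchyma),
  and (5) a morphological closing with an ellipsoidal structuring element
  of 4.5 mm radius scaled by the voxel spacing to repair the boundary.
* **Geometry.** Volumes are resampled to 3 × 1.5 × 1.5 mm (trilinear for
  intensities, nearest-neighbour for masks; output shape
  round(shape·spacing/target)). A case is split along the axial axis into
  two 48 × 192 × 192 subcases (centered crop/pad per half, pad value
  −1000 HU, with an offset record so mask coordinates map back exactly).
  Classification inputs are 16 × 48 × 48 ROIs centered on the rounded
  voxel centroid of a nodule component, padded with −1000 HU at borders.
* **Annotation rules.** A voxel enters the consensus mask when at least
  3 distinct raters marked it. Per-nodule malignancy on the 1–5 scale is
  reduced across raters by the lower median; ≤ 2 is benign, ≥ 4 malignant,
  and a median of 3 ("uncertain") excludes the nodule. Diameter bins:
  micro d ≤ 5, small 5 < d ≤ 10, nodule 10 < d ≤ 30, mass d > 30 mm.

## Segmentation network (3-D Res U-Net)

A 4-level encoder–decoder. Each level is a residual unit: mapping path
Conv3×3×3 → IN → ReLU → Conv3×3×3 → IN; identity path Conv1×1×1 → IN →
ReLU (present in every unit, so channel counts always match); sum, then
ReLU. IN is instance normalization (per-sample, per-channel, ε = 1e-5, no
affine parameters) for batch-size robustness. Encoder: unit then 2×2×2
max pool, channel ladder 8-16-32-64 into a 128-channel bottleneck unit.
Decoder: transposed convolution (k = 2, s = 2) → IN → ReLU, concatenation
with the same-resolution encoder feature, then a residual unit that halves
the channels. Output head: 1×1×1 convolution + sigmoid. For a
1 × 48 × 192 × 192 input the bottleneck is 128 × 3 × 12 × 12 and the
output matches the input resolution. Weights are Xavier-uniform.

**Output-bias prior.** The output convolution's bias is initialized to −4
(≈ the background log-odds: nodules occupy ~0.2 % of a volume). Starting
from P ≈ 0 everywhere keeps the early Dice phase out of its well-known
diffuse-prediction stall, in which the per-voxel Dice gradient is nearly
uniform and the optimizer cannot sparsify the prediction. With zero bias
the scaled-down runs plateau at a soft Dice loss near 0.98.

**Loss schedule.** Binary cross entropy (summed over voxels; gradient
w.r.t. the logit is P − T) for the first 3 epochs as a stabilizing warm-up,
then soft Dice loss 1 − (2|T·P| + s)/(|T| + |P| + s) with smoothing
s = 1e-5 in numerator and denominator. The active loss is a pure function
of (epoch, bce_epochs). For the optimizer step the BCE gradient is divided
by the voxel count so step size is independent of volume size; the logged
loss is the summed form. A squared-denominator Dice variant
2|T·P|/(|T|² + |P|²) is also provided: its classic closed-form voxelwise
gradient 2T(T² − P²)/(T² + P²) is kept as a documented reference
(`dice_grad_reference`); dividing that expression by (T² + P²) gives the
exact derivative, which the tests verify against numerical differentiation.

**Training.** Adam, initial learning rate 1e-2 stepped to 1e-3 and 1e-4
(default milestones at 3/8 and 6/8 of the run, i.e. epochs 24 and 48 of
64), batch size 6, 64 epochs — the reference configuration. The
CPU-sized configuration (`SegTrainConfig.desk()`) keeps the same schedule
shape but uses batch size 2 and 80 epochs with milestones at 0.45/0.75,
chosen so the optimizer gets enough steps per epoch on a 15-volume cohort.

## Classification network (3-D ResNet50)

ResNet50's bottleneck composition (block counts 3-4-6-3, expansion 4) with
three modifications for small, spatially rich lesions in thin ROIs:
all-3-D convolutions; reduced kernels where a large receptive field would
mostly see padding (stem 3×3×3 instead of 7×7; the middle convolutions of
the last two stages are 1×3×3, sparing the 16-slice axial axis); and no
max pooling — all downsampling is by strided convolution with stage
strides (1,1,1), (1,2,2), (2,2,2), (2,2,2), leaving a 4×6×6 grid for a
16×48×48 ROI. The exact reduced kernel sizes and stride placement are
package choices (the modification list fixes the intent, not the numbers).
Global average pooling (retained: the pooling removal targets the lossy
early max pool) feeds a 2-way linear head with log-softmax; training
minimizes mean negative log likelihood over one-hot labels (Adam, lr 1e-4,
batch 16, 52 epochs by default). Normalization is instance normalization,
matching the segmentation network. Predicted label is the argmax;
a tie is called malignant (the conservative direction clinically).

## Phantom generator

Each phantom paints, in order: air background (−1000 HU), a soft-tissue
body ellipsoid (+40), two lung ellipsoids (−850) eroded to keep a
soft-tissue shell around them, an optional bed slab (+200) posterior to
the body, optional vessels (+50; random polylines of sphere stamps,
radius 1–2 mm, clipped to the lungs), and nodules at a uniform HU drawn
from −100..+100. Benign nodules are exact spheres. Malignant nodules are
spheres at 0.88 of the nominal radius with a low-frequency radial
perturbation (±6 %) and 4–10 radial spikes reaching 1.3× the base radius —
a shape signal (smooth vs spiculated) the classifier can learn, echoing
the radiological association between spiculation and malignancy.
Placement requires the full nodule inside a lung (clearance at least the
radius, via a distance transform; 100 retries then a hard error naming
seed and nodule index). Gaussian noise (default sd 20 HU, a realistic
soft-reconstruction level) is added last; masks reflect the exact painted
geometry. Four synthetic raters each contribute a mask (randomly eroded,
kept, or dilated by one voxel) and a malignancy level drawn near the true
trait (benign: 1/2/3 with probability .45/.45/.1; malignant: 3/4/5 with
.1/.45/.45), so consensus and label-aggregation rules are exercised with
realistic disagreement.

What the phantoms do **not** emulate: real parenchymal texture, partial
volume and reconstruction-kernel effects, beam hardening, motion,
mediastinal anatomy, pleural-wall-attached or ground-glass nodules.
Passing the synthetic suite therefore demonstrates that the pipeline's
mechanics (geometry, losses, optimization, evaluation) are correct and
that the networks can learn contrast- and shape-based lesion signals at
small scale — not clinical-grade performance.

## Network engine

The networks run on a compact numpy engine (`lungnodule.nn`): 3-D
convolution, transposed convolution, max pooling, instance normalization,
ReLU/sigmoid, a linear head, Xavier initialization and Adam, all with
explicit hand-derived backward passes validated against central finite
differences in float64. Convolutions use strip-blocked im2col kernels
(numba) so each output row strip costs one cache-resident gather plus one
small BLAS matmul; a pure-numpy im2col path computes identical results
and serves as a cross-check. Arithmetic is float32; given a seed, runs
are deterministic on a fixed platform. One consequence of normalization:
a convolution bias feeding an instance norm has exactly zero gradient
(the norm removes additive constants), which the gradient tests account
for.

## Scaled-down experiment sizes

CPU-sized runs use: 20 single-nodule phantoms of 32 × 64 × 64 voxels at
3 × 1.5 × 1.5 mm with diameters 12–25 mm (15 train / 5 held-out, the last
five generator seeds held out); a quarter-width segmentation network
(ladder 2-4-8-16, bottleneck 32) trained with the BCE→Dice schedule and
scored by majority over 3 training seeds against a held-out mean Dice of
0.8 — the reference bound for nodules above 10 mm. Classifier experiments
use 1/16-width models: memorization of 8 ROIs (30 epochs) and
smooth-vs-spiculated separability on 24 balanced ROIs (≥ 0.8 training
accuracy within 10 epochs). The separability check runs at this reduced
cohort/width because a quarter-width model on 60 ROIs needs hours of CPU;
the property being demonstrated (the shape signal is learnable from the
ROI alone) is the same.

## Numerical choices and degenerate inputs

* Dice on two empty masks is undefined and raises; precision with an empty
  prediction and recall with an empty reference are reported as missing
  (NaN) rather than 0.
* Binarization threshold for probability maps is 0.5 with ties included.
* BCE probabilities are clipped to [1e-7, 1 − 1e-7]; NLL clips a zero
  true-class probability and warns.
* ROC is a threshold sweep over distinct scores; tied scores move
  diagonally so the trapezoid rule gives ties half credit, making the AUC
  equal to the pairwise rank statistic (verified exhaustively for small
  inputs).
* `dice_grad_reference` returns 0 where T = P = 0 (limit convention).
* Per-nodule segmentation metrics are computed inside the truth
  component's bounding box padded by 6 voxels, so one nodule's score is
  not diluted by distant false positives; per-category tables aggregate
  by mean.
* Resampling uses `scipy.ndimage.zoom` with `grid_mode=True` so the
  physical extent is preserved; mask resampling is order-0.

## Known limitations

* The engine is CPU-bound; reference-width training (48 × 192 × 192
  batches) is out of reach, which is why training claims are made at
  quarter width on subvolumes.
* Held-out Dice on 5 phantoms has high variance; single spiculated
  nodules near the small end of the diameter range can be missed by a
  quarter-width model trained on 15 samples, and the 3-seed majority
  absorbs exactly this variance.
* DICOM support covers plain axial CT series with rescale slope/intercept
  and consistent slice spacing; no multi-frame, gantry-tilt or
  orientation-resampling handling.
* The lung-parenchyma workflow assumes the lungs do not touch the volume
  faces, which holds for whole-thorax acquisitions and the phantoms but
  not for arbitrary crops.
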