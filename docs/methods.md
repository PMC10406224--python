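# Methods

`ichseg` implements a label-efficient pipeline for semantic segmentation of
intracranial hemorrhage (ICH) in non-contrast head CT: a slice-wise 2D U-Net
fine-tuned with a weighted mixed-slice Dice objective, optionally initialized
from one of six self-/weakly-supervised pretext tasks, masked by a
dual-window intracranial-cavity model, and evaluated volume-wise.  A
synthetic head-CT phantom generator makes every stage testable end to end on
a laptop-class CPU without any data download.

## The segmentation model

Volumes are processed slice by slice.  Each slice is windowed to the
[-50, 150] HU contrast window (clip + linear rescale to [0, 1]), which
brackets the 40-90 HU range typical of acute hematoma while retaining
soft-tissue context.  The backbone is a classic U-Net: five encoder blocks
(two 3x3 convolutions with batch-norm and ReLU; channels double across a
block; 2x2 max-pooling between blocks) and four decoder blocks (kernel-2
stride-2 transposed convolution, concatenation with the matching encoder
skip, two convolutions halving the channels).  With 32 base channels the
encoder produces 32-64-128-256-512-channel maps and a 256x256 input yields a
16x16x512 bottleneck; the output is a single sigmoid map thresholded at 0.5.
All runs use Adam (beta = 0.9/0.999, eps 1e-8), initial learning rate 1e-3
decayed by 0.96 per epoch, and an L2 penalty of 1e-6.

The network core is a compact CPU implementation (im2col convolutions,
explicit analytic backward passes, seeded Kaiming-uniform initialization).
Each layer's backward pass is verified against float64 central finite
differences in the test suite.

### Fine-tuning objectives

Two baselines bracket the supervision design:

* **ICH-only** — train on hemorrhage-containing slices only, soft Dice loss
  `1 - (2<p,t> + s) / (|p|^2 + |t|^2 + s)`;
* **Mixed** — all hemorrhage slices plus twice as many hemorrhage-free
  slices (sampled once, uniformly without replacement), where a slice with
  empty ground truth contributes its Dice loss down-weighted by alpha = 0.2.
  The batch value is the mean over slices.

**Dice smoothing.** The smoothing constant defaults to `s = 1` (the
conventional V-Net-style smooth term), not a token epsilon.  This is a
deliberate and load-bearing choice: for an empty-ground-truth slice the
Dice loss is `1 - s/(sum p^2 + s)`, whose gradient scales like
`s / (sum p^2 + s)^2`.  As `s -> 0` the loss saturates at 1 with a
*vanishing* gradient, so down-weighted normal slices would be training
no-ops and the mixed objective could never learn to reject healthy slices —
we observed exactly this failure (healthy volumes flooded with false
positives) before fixing `s`.  With `s = 1` an empty slice exerts a real
pull toward the empty prediction.  The hand-checkable fixture values in the
tests evaluate the loss with `s = 0` explicitly.

### Precise-BN recalibration

Desk-scale schedules take tens to a few hundred optimizer steps, far too few
for momentum-averaged batch-norm running statistics (momentum 0.1) to track
the final weights; evaluation-mode predictions were visibly miscalibrated
relative to training-mode predictions.  After every training loop the
running statistics are therefore replaced by dataset statistics computed
under the final weights (averaged batch moments over the training set), the
standard "precise BN" procedure.

## Pretext tasks and transfer

Six pretext tasks produce a checkpoint whose tensors initialize the
downstream U-Net (nothing is frozen afterwards):

| task | network | objective | transferred scope |
|---|---|---|---|
| context restoration | full U-Net | MSE reconstruction of an image corrupted by N = 20 random 20x20 patch-pair swaps | full network |
| global contrastive | encoder + MLP head (512-512-128) | NT-Xent, temperature 0.1, cosine similarity, mini-batch comparison set, views under T_G | encoder |
| local contrastive | encoder + 3 decoder blocks (skips kept) + 1x1 conv head (64-128-32) | InfoNCE over N_r = 20 non-overlapping 3x3 feature-map regions; positives = same location across T_L views; encoder frozen and initialized from the global checkpoint | encoder + partial decoder |
| binary classification | encoder + GAP + MLP (512-1024-256-2), softmax | cross-entropy on slice-level ICH presence | encoder |
| multi-label CE | encoder + GAP + MLP (...-7), sigmoid | class-weighted binary CE on the 7-way target (no-ICH, ICH, 5 subtypes); weights = inverse class frequency on the training split, normalized to mean 1 | encoder |
| multi-label DL | same head | Dice loss on the 7-vector | encoder |

The swap corruption redraws a swap's second patch until the pair is
disjoint, so the corrupted image is always an exact pixel permutation of
the original (successive swaps may overlap freely).  The augmentation
chains: T_G = translate +-15%, rotate +-90 deg, scale [0.8, 1.2],
horizontal flip p = 0.5, contrast/brightness jitter p = 0.5, Gaussian blur
p = 0.5, random crop-and-resize; T_L drops the flip (feature localization
is the point of the local task) and limits rotation to +-45 deg.
Magnitudes the protocol leaves open are set to the conventional
contrastive-learning values and exposed in the configuration dataclass: contrast
factor [0.8, 1.2], brightness offset [-0.1, 0.1] on the [0, 1] scale, blur
sigma [0.1, 2.0], crop area fraction [0.6, 1.0]; composition order is fixed
as translate -> rotate -> scale -> flip -> photometric -> crop/resize.
Pretext slice pools are class-balanced (equal ICH and no-ICH slice counts)
before training.

Printed formulations of the two contrastive losses leave the index
conventions ambiguous; this package follows the standard constructions:
the global loss sums the anchor cross-entropy over all 2N views, and the
local loss takes as negatives all other sampled region descriptors from
both views.  Both implementations are checked against independent
double-loop oracle evaluations to 1e-6.

## Intracranial-cavity masking (ICM)

Hemorrhage exists only inside the skull, so voxels outside the intracranial
cavity are noise by construction.  Two U-Nets are trained on complementary
windows of the same slices — tissue [0, 600] HU and bone [150, 650] HU —
each on the Dice loss against the cavity ground truth; the cavity mask is
the union (logical OR) of their predictions thresholded at 0.5.  The mask
is applied at evaluation only: whenever the ground truth lies inside the
cavity, masking provably leaves TP and FN unchanged and can only remove
false positives (recall unchanged, precision non-decreasing) — asserted as
a property test.

## Evaluation

TP/FP/FN are aggregated over whole volumes and stabilized with epsilon = 1:

    Dice      = (2 TP + eps) / (2 TP + FP + FN + eps)
    Precision = (TP + eps) / (TP + FP + eps)
    Recall    = (TP + eps) / (TP + FN + eps)

so a healthy volume with no detections scores 1.0 on all three.  Metrics
are reported twice — over all volumes and over hemorrhage volumes only —
because the all-volumes average rewards under-detection on healthy scans.
Cross-validation splits at the volume level (all slices of a scan share a
fold), stratified so hemorrhage volumes are spread as evenly as possible;
fold sizes differ by at most one.  Method pairs are compared with
independent two-sample Welch t-tests (unequal variances,
Welch-Satterthwaite df) per metric; identical zero-variance samples return
p = 1 by convention.  Per-subtype summaries attribute a volume's Dice to
every subtype it contains (the ground truth is binary ICH, not re-masked
per subtype).

## The phantom generator

The generator emulates the structure the pipeline relies on, not CT
physics: air background (-1000 HU), elliptical high-attenuation skull shell
(+1000 HU), brain parenchyma (+30 HU), CSF ventricles (+5 HU), i.i.d.
Gaussian HU noise (sd 4), and hyperdense lesions drawn per-voxel from
[40, 90] HU.  Subtype geometries are cartoons of the clinical patterns:
IPH an elliptical parenchymal blob; IVH a blob clipped to the ventricles;
SDH a thin crescent along the inner skull boundary (thickness 9-15% of the
cavity radius); EDH a thicker lens over a shorter arc (16-26%); SAH an
irregular speckled band near the cortical periphery.  Rim-lesion widths
matter at desk resolution: bands much below ~2 px are indistinguishable
from the bilinear partial-volume band at the skull-brain boundary, so the
defaults model the moderate-to-large collections that are realistic
segmentation targets.  Default volumes are 64x64x24 (real scans have ~35
slices; too few slices starve slice-wise training), with 1-3 lesions per
hemorrhage volume and subtype frequencies (IPH 0.30, IVH 0.15, SAH 0.20,
SDH 0.20, EDH 0.15) roughly tracking the prevalence mix of public ICH
segmentation datasets.  Everything is seeded: a dataset regenerates
bit-identically from (config, seed).

What the phantom does *not* emulate: beam hardening, reconstruction
kernels, partial-volume anatomy, skull-base complexity, pathology mimics
(calcification, tumor), or realistic lesion shape statistics.  Passing
desk-scale tests therefore demonstrates that the pipeline's machinery is
correct and that its comparative behavior (e.g., mixed > ICH-only
precision) reproduces under controlled conditions — not clinical-grade
performance.

## Desk-scale profile

Unit and acceptance tests run a reduced profile chosen once: 64x64 slices,
base-8 U-Net (~340k parameters), 10 fine-tuning epochs, batch size 2.  At
this epoch budget the binding constraint is the optimizer step count, not
the epoch count, hence the small batches (the full-scale protocol's batch
16 with 100 epochs corresponds to ~50x more steps).  The full-scale
hyperparameters (256x256, base 32, batch 16/32, 50-100 epochs) remain the
documented defaults of the configuration dataclasses.

## Known limitations

* The numpy core is CPU-only and ~2 orders of magnitude slower than a GPU
  framework; it is meant for correctness-first experimentation at phantom
  scale.
* At desk scale, encoder-only transfer (classification/contrastive
  pretexts) is not beneficial and can be actively harmful: an encoder
  trained under global average pooling develops spatially diffuse
  "hemorrhage present" features over the whole cavity, a fresh decoder
  wired to them starts out predicting hemorrhage broadly, and at a few
  hundred optimizer steps fine-tuning cannot reliably unlearn this bias
  (while full-scale schedules, with ~50x more steps and far larger pretext
  pools, can).  Full-network transfer (context restoration) shows no such
  pathology.  The acceptance script measures and reports the transfer win
  rate rather than assuming the full-scale direction holds here.
* The Welch comparison treats methods as independent samples (the volumes
  are actually shared across methods); a paired test would be more
  powerful but is not what the protocol describes.
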