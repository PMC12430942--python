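# Methods

This note documents the models and procedures the package implements, the
choices that were genuinely open, and what the synthetic experiments do
and do not show.

## Problem setting

A segmentation network trained on one imaging domain (e.g. abdominal CT)
degrades badly on another (e.g. MR) because absolute intensities and
contrasts change while anatomy does not.  The package addresses this in
two independent, combinable stages:

1. **Domain-generalized pre-training** — feed the network inputs that are
   stable across domains: randomized intensity remappings (GIN) enlarge
   the appearance manifold seen in training, and the self-similarity
   context descriptor (SSC) replaces absolute intensity with local
   self-similarity structure.
2. **Source-free test-time adaptation (TTA)** — for each unseen target
   scan, briefly optimize the network so that its predictions on two
   differently spatially-augmented views of that one scan agree.

## GIN intensity augmentation

`GIN(x) = alpha * g(x) + (1 - alpha) * x`, with `g` a shallow
convolutional network re-randomized at every training iteration and
`alpha ~ U[0, 1]` drawn per augmented volume.  The architecture of `g` is
an open choice; this package uses 4 convolutions (kernel 3, 8 hidden
channels, leaky rectifier slope 0.2), weights from a scaled normal
initialization, with edge-replicate padding (a constant field maps to a
constant field) and the output rescaled to the input's mean and standard
deviation so augmented images stay in a trainable range.  These are
declared defaults, not claimed fidelity to any reference architecture.

## SSC descriptor

For every voxel, the six axis neighbors at `patch_distance` (default
1 vox) form a neighborhood; the descriptor takes the 12 unordered pairs
of *non-opposite* neighbors (the pairs that diagonally connect adjacent
patches, deliberately ignoring the center patch), computes the
sum-of-squared-differences `SSD` between the two patches of each pair
(patch size 1 vox by default), and emits

    SSC_channel = exp(-SSD / sigma^2)

Channel order is fixed by lexicographic enumeration of the offset list.
Design points:

* **Noise estimate `sigma^2`** — "the mean of all patch distances" is
  read per voxel (mean of that voxel's 12 SSDs); an image-global scalar
  is available via `sigma_mode="global"`.  The per-voxel reading
  preserves local contrast invariance, which is what makes the
  descriptor modality-robust.
* **Floor** — `sigma^2` is floored at `max(1e-6 * global mean SSD,
  1e-12)`; flat regions therefore give `exp(0) = 1` rather than 0/0.
* **Boundaries** — shifted patches use edge-replicate padding so the
  output grid equals the input grid.
* **Invariance** — both SSD and `sigma^2` scale by `a^2` under
  `x -> a x + b`, so the descriptor is exactly invariant to affine
  intensity changes (up to the floor, which is relative and scales too).
  This is asserted to 1e-5 in the tests.

## Spatial-consistency TTA

For one unlabeled target volume, each optimization step draws
`patches_per_step` random patch locations.  Each patch is viewed through
two random affine transforms (rotation ±10°, isotropic scale 0.9–1.1,
shear ±0.05, translation ±5 % of the patch extent — mild, invertible,
configurable; magnitudes are engineering defaults).  The transform acts
on the patch sampling grid, so both branches see differently distorted
views of the same region.  Both views pass through the network; both
predictions are warped back through the exact inverse transform.
Warping is multiplication by a sparse trilinear-interpolation matrix, so
its gradient is the transposed matrix.  Voxels whose pull-back
coordinates leave the patch grid carry no content; the out-of-field
marker is a boolean validity mask (not a sentinel value, which could
collide with real probabilities), and the consistency mask is the AND of
the two branch masks.  Chained warps propagate validity: a voxel that
interpolates from any invalid voxel is invalid.

The masked predictions are compared with the consistency Dice loss

    l = 1 - (1/|C|) sum_C (2 sum_w yA yB + e) / (sum_w yA^d + yB^d + e)

with exponent `d = 2` by default: then identical predictions incur
exactly zero loss (the loss landscape is zero on the diagonal), whereas
`d = 1` additionally rewards confident predictions.  `e = 1e-5` is a
declared stability default.  The background channel is excluded from the
channel set by default; the subset is configurable.

Optimization follows the method's standard operating point: AdamW,
learning rate 1e-5, weight decay 0.01, no scheduling, exactly 12 steps,
each accumulating the gradients of 16 patches into one update (the
accumulation counters overfitting to any single patch's field of view).
By default gradients flow only through branch A — branch B's prediction
is detached and acts as a fixed target — and both branches are spatially
augmented with no intensity augmentation, the configuration found to be
the best trade-off for conventionally and generalized pre-trained models.
Adaptation always runs on a copy: the base model is reusable sample after
sample, and the interface accepts only the model and the single target
volume (source-free by construction).  Ensembling adapts each
independently pre-trained member with its own randomness stream and
averages softmax outputs before the argmax.

## Backbone and pre-training

The backbone is deliberately compact: a 3-level 3D U-Net (one 3^3
convolution + per-channel normalization + leaky rectifier per level,
8/16/32 channels, skip connections by concatenation, 1^3 classification
head), runnable on one CPU.  The method under study lives in the input
features and the adaptation loop and treats the backbone as given; the
compact network is a stand-in for production-scale backbones.  The
network, its training, and the differentiable adaptation loop run on a
small reverse-mode autodiff engine written for this package and validated
against finite differences.

Supervised pre-training uses Dice + cross-entropy on class-balanced
random patches (half of the patches centered on a random foreground
voxel), Adam at 2e-3, 24 epochs of 30 iterations with 2 patches per
iteration (1440 patches), patch size 24^3.  The schedule length was set
so that raw-intensity training converges dependably across seeds on the
default phantom cohort (shorter schedules leave it stuck at low source
Dice for some initializations); the adaptation stage presumes an
adequately converged base model.  In `gin+ssc` mode GIN is applied to the full
volume and SSC computed on the GIN output before patch extraction, so
patch borders see correct descriptor neighborhoods.  Volumes are z-score
normalized per volume before the feature pipeline.  GIN is train-time
only; SSC changes the input channel count (1 -> 12) and is therefore
active at training and inference.

Sliding-window inference tiles patches with stride 5/6 of the patch size
and averages softmax outputs on overlaps.  Because per-channel
normalization statistics depend on the patch content, tiled and
whole-volume inference agree only approximately (mean absolute
probability difference of a few percent on the compact backbone); this
field-of-view sensitivity is inherent to instance-style normalization
and is asserted at its measured scale in the tests.

## Synthetic paired-domain phantoms

The generator renders one random blob geometry (4 foreground classes)
through two intensity lookups: a monotone CT-like source ramp and a
non-monotone MR-like target map in which some classes keep an intensity
near their source appearance and others swap ranks.  The target map must
not be an affine function of the source map (validated): the descriptor
is affine-invariant by construction, so an affine gap would be trivially
closed and prove nothing.  The target additionally receives a smooth
multiplicative bias field (exponentiated low-order polynomial) and each
domain its own additive Gaussian noise.  Class means are validated to be
separated by at least twice the noise level.

Two generator decisions deserve emphasis:

* **Class identity carries intensity-invariant signatures.**  Each class
  has a characteristic blob size/elongation range and a class-specific
  texture grating present in both domains.  If class identity were coded
  *only* in absolute intensity, no intensity-invariant feature could
  recover it even in principle, and descriptor-based generalization
  would be untestable.  Real anatomy carries exactly such shape and
  texture regularities.
* **The gap is severe but partial.**  The default target map degrades a
  source-trained raw-intensity model by well over 20 Dice points while
  leaving it above chance, mirroring cross-modality transfer of real
  non-generalized models (severely degraded, not at zero).  A full label
  permutation would drive the base model to 0 Dice, a regime from which
  no consistency signal can recover anything.

All randomness flows from one seed through named substreams (geometry,
intensity, noise).  Datasets are written as uncompressed NIfTI so re-runs
are byte-identical.

## Evaluation

Dice is reported in percent; 100 is declared when a class is absent from
both maps, 0 when absent from exactly one.  HD95 pools the directed
surface distances of both directions into one set and takes the 95th
percentile with linear interpolation between order statistics (the
directed-max variant is a different convention; the pooled one is stated
so numbers are reproducible).  Surfaces are boundary voxels (6-
connectivity, array borders count as boundary); distances are in
millimetres via the voxel spacing.  A class absent from either side is
undefined and excluded from means with the exclusion counted.  Cohort
improvements are judged with the one-sided Wilcoxon signed-rank test with
stars at 0.05 / 0.01 / 0.001; an all-ties comparison is reported as p=1.

## The desk-scale study and its limits

`dgtta.experiments.run_domain_shift_study` generates 8 source training, 6
source test, and 6 target test phantoms at 64^3, trains a raw-intensity
and a `gin+ssc` model (1440 patches each), evaluates the cross-domain
drop, and adapts the raw-intensity model per target sample at the
standard TTA operating point.  These problem sizes are the package's
deliberate desk-scale defaults: large enough that the directional claims
(a large cross-domain gap; generalizing features retaining target
accuracy) are stable across seeds, small enough to run on one CPU in
minutes.

What the phantom study shows: the descriptor+augmentation pipeline
retains most of its accuracy across a non-affine intensity gap that
collapses a raw-intensity model; the adaptation loop reduces the
consistency objective deterministically and reproducibly.  What it does
not show: generalization to real anatomy, orientation or resolution
gaps, or the adaptation gains reachable with production-scale backbones —
at this parameter count and step budget the weight displacement of the
adaptation (learning rate x steps ~ 1e-4) changes per-sample Dice only
marginally, so the per-sample Dice deltas carry no reliable sign and the
cohort-level signed-rank test on the Dice gain is expected to come out
null here even though the consistency objective itself descends.  Large,
deep backbones — where a small relative weight change propagates through
many layers and strong learned shape priors make two-view agreement and
segmentation quality pull in the same direction — are the regime in which
this adaptation is known to recover substantial accuracy; reproducing
that regime is outside the desk-scale scope.

## Numerical choices

* Network compute in float32 (float64 available via config; the
  gradient-equivalence tests run in float64).
* Probability fields are renormalized per voxel after linear-interpolated
  warps/resampling to preserve the simplex invariant.
* Resampling to a uniform voxel grid (default 1.5 mm isotropic for
  phantom data) uses linear interpolation for images, nearest for labels;
  the output grid is `round(size * spacing / target)` per axis.
* Empty consistency masks (fully disjoint fields of view) yield zero loss
  with a warning so the patch loop skips degenerate draws.
* Orientation is taken as stored in the NIfTI header; no RAS
  canonicalization.
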