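# Methods

This note documents the models, numerical procedures and design choices behind
`hepaseg`, a toolkit for automatic segmentation of colorectal liver metastases
(CRLM) and thermal-ablation zones on contrast-enhanced CT (CECT).

## Problem setting

CRLM and post-ablation zones appear hypo-enhanced on portal-venous CECT,
often with a hyper-enhancing rim.  Segmenting them is hard for two reasons:
lesions are small relative to the liver (severe class imbalance — a network
that predicts "normal liver" everywhere scores deceptively well), and lesion
borders fade gradually into parenchyma, especially at the superior/inferior
poles where partial-volume effects dominate.  The toolkit addresses the first
problem with disease-centred training slabs and the second with
seed-and-threshold growth on the network's probability output.

## Pre-processing

**FWHM intensity normalization.**  CT intensities are standardized per
patient using only in-liver statistics: the histogram (default bin width
1 HU) of HU values inside the liver mask is scanned from its highest bin for
the two half-maximum crossings (linear interpolation between bin centres);
the full width at half maximum (FWHM) between them gives the scale
`sigma = FWHM / (2 sqrt(2 ln 2))` and the crossings' midpoint gives the
centre.  Normalized intensity is `(HU - centre)/sigma` inside the liver and
exactly 0 outside.  Using the FWHM rather than a global mean/sd makes the
estimate insensitive to the long tails contributed by vessels, lesions and
calcifications.  The crossing midpoint is used as the centre (rather than the
mode bin itself) because the crossings sit on the steep flanks of the peak:
their midpoint localizes the parenchyma centre to a fraction of a bin, while
the mode bin of a 1-HU histogram fluctuates by several HU at realistic voxel
counts.  Degenerate histograms (near-constant intensities, no half-maximum
crossing on one side) raise an error rather than returning a junk scale.

**Resampling.**  Volumes are resampled with linear interpolation to a target
spacing (default 1.0 × 0.75 × 0.75 mm); the output size per axis is
`round(n · s_in / s_target)`, minimum 1.  Ground-truth masks are resampled
with the same linear interpolation and re-binarized at 0.5 so their
boundaries move with the image content; predictions are mapped back to each
case's original grid with nearest-neighbour interpolation before any metric
is computed.

## Training slabs

One fixed-size slab (default 32 × 120 × 120 voxels) is extracted per
connected disease site (26-connectivity by default), centred on the site's
voxel centroid, shifted inward at volume boundaries, and zero-padded only
when the whole volume is smaller than the window.  Sites larger than the
window are covered by `ceil(extent/window)` tiles per axis with
linspace-distributed starts, which guarantees every disease voxel of the
site falls in some window.  All disease voxels inside a window are labelled,
not only the seeding site, so neighbouring lesions are never marked
"normal".  Augmentation is restricted to axis flips/mirrors, applied
on the fly with per-axis probability 0.5 from a seeded generator.

## Architectures

All models take two channels — normalized image and binary liver mask — and
emit per-voxel two-class probabilities (softmax) at the input resolution.
Variable input sizes are handled by reflect-padding to the model's pooling
multiple and cropping the output; training computes the loss only on
unpadded voxels.

**3D U-Net family.**  `layers` counts the poolings (factor 2 per axis);
filters double per level up to `filters_max`; conv blocks per level grow by
`conv_block_increase` (the "convolution lambda") up to `conv_blocks_max`.
Block styles: *standard* = conv(3³, bias) → BN → ReLU; *residual* adds the
block input (1×1×1-projected on channel change) to the normalized
convolution output before activation; *dense* concatenates every previous
same-level output, then BN → ReLU → conv, with block *k* emitting
`filters + k · growth_rate` channels.  An unbounded dense configuration
(no `filters_max`, no `growth_rate`) is rejected.

**Hybrid W-Net.**  Two coupled networks shaped like a W: a 2D U-Net whose
encoder is the DenseNet-121 topology (bottleneck dense layers, 0.5
compression; single-channel CT replicated ×3 so pretrained RGB weights would
remain usable) and whose decoder upsamples through five stages (nearest ×2,
skip concatenation from the matching encoder stage, two 3×3 conv + BN + ReLU;
channel schedule 256/128/64/32/32) to 32 feature maps per slice; these are
concatenated with the image and liver channels into a two-level 3D dense
network (2 conv blocks at full resolution, 3 at half, mirrored decoder).
The 3D dense connections are *global*: every convolution at a given spatial
scale consumes the concatenation of all previous same-scale outputs across
the entire 3D network — encoder outputs feed decoder convolutions directly —
and the classification head sees the full concatenation.  ImageNet weights
for the encoder are not bundled; requesting a pretrained file that does not
exist raises an error, and random initialization is the explicit default.

**Parameter accounting.**  Counts come from an analytic per-layer sum over
the declarative graph and must equal the runtime array sizes exactly; BN
running statistics and frozen weights count as non-trainable.  The 2D
encoder reproduces the canonical DenseNet-121 figures exactly (7,037,504
parameters, 83,648 non-trainable).  The source publication for this model
family reports 14,497,600 total / 14,408,960 trainable parameters but leaves
the 2D decoder unspecified and prints two different values for the 3D
initial-filter count (8 in the architecture figure, 32 in the results text).
With this package's decoder reconstruction the two readings give 13,875,092
and 15,335,636 total parameters respectively — bracketing the published
figure with residuals of −4.3% and +5.8%.  A search over ~40k natural
decoder variants (channel schedules, convs per stage, bias usage,
transposed-conv vs upsampling, skip sets, BN placement, dense carry rules)
found none matching both the published total and the batch-norm channel
budget implied by the published non-trainable count, so the reconstruction
above is retained and the residual documented here.

## Runtime

The models run on a small NumPy layer runtime written for this package
(channels-last tensors; convolutions evaluated as shift-and-matmul sums over
kernel offsets; exact analytic backward passes, verified against central
differences; TF-convention batch norm with eps 1e-3, momentum 0.99; Adam).
Frozen batch-norm layers run in inference mode and do not update their
moving statistics, which makes the freeze contract exact (byte-identical
weight digests).  All randomness flows through seeded NumPy generators, so
single-threaded runs are bit-reproducible.

## Training protocol

Four strictly ordered phases, each optimizing per-voxel sparse
cross-entropy with Adam under a triangular cyclical learning rate:

1. `decoder2d_only` — 2D decoder + head train against the slice-wise output;
   encoder and 3D network frozen.
2. `full_2d` — whole 2D network trains; 3D frozen.
3. `dense3d_only` — 3D network trains on the extracted 2D features; all 2D
   weights frozen.
4. `end_to_end` — everything unfrozen.

Per phase, the learning-rate band is found with an exponential sweep: the
largest rate whose exponentially smoothed loss (factor 0.98, bias-corrected)
stays within 20% of its running minimum becomes `lr_max`, with
`lr_min = lr_max/10`.  Because the smoothed curve reacts slowly on short
sweeps, the sweep additionally stops when a raw loss spikes above 2× the
running raw minimum, and every sweep step uses the same batch (batch-to-batch
loss variation on small cohorts would otherwise drown the divergence signal).
Training phases sweep rates up to 0.05 by default — a one-step-per-rate sweep
cannot expose multi-step divergence of a freshly initialized subnetwork, so
the never-diverged fallback must itself be a usable Adam ceiling.  The sweep
restores all weights and optimizer state afterwards.

Validation during training is the patient-wise mean Dice of the thresholded
(0.5) prediction on whole livers at training resolution — never on slabs; a
phase stops after 5 evaluations without improvement (configurable) and
reloads its best weights.  Epoch counts and cycle length are pragmatic
defaults, exposed in `TrainingPhase`.  Training is repeated from 3 random
restarts by default and the best run selected by validation Dice (ties to
the lowest seed).  Mixed precision is not used: full float32 keeps CPU runs
deterministic.

## Post-processing

The network's disease probability is binarized by seeded growth: voxels with
probability ≥ *seed* mark confident cores, grown through the connected
region (26-connectivity default) with probability ≥ *threshold*; components
above threshold containing no seed voxel are discarded.  Defaults
(0.67, 0.30) are the published grid-search optimum.  `tune_seed_threshold`
re-derives such an optimum exhaustively over seed 0.25–0.95 and threshold
0.20–0.80 in 0.01 steps (pairs with seed < threshold are skipped as
invalid), maximizing mean patient Dice by default (pooled "global" Dice via
flag — which of the two the original tuning used is not stated); ties go to
the smallest seed, then the smallest threshold.

## Evaluation

All metrics run at original image resolution.  Dice is `2|A∩B|/(|A|+|B|)`
(empty–empty = 1, empty-vs-nonempty = 0, the LiTS-style convention); global
Dice pools all patients' masks before the ratio.  Median surface distance
takes boundary voxels (≥1 face-adjacent background voxel), pools the
symmetric nearest-surface distances in mm (KD-tree exact), and reports the
median; it is undefined (reported missing) when either mask is empty.  Each
ground-truth site is matched to the predicted component with the nearest
centroid (a predicted component may serve several sites); site Dice/distance
use only the matched component, while detection uses the union of all
predicted voxels: a site counts as detected when ≥45% of it is covered
(boundary inclusive).  False-positive voxels (prediction minus truth) split
into *erroneous* volume — voxels of predicted components with zero
ground-truth overlap, whose count is the "false-positive discoveries" — and
*over-segmentation* volume (the remainder); the two sum to the total
false-positive volume by construction.  Site tables stratify by
sphere-equivalent diameter `(6V/π)^{1/3}` (the publication never defines its
diameter; the sphere-equivalent is the only measure derivable from a
volume alone), default bins <15 / ≥15 mm.

## Synthetic phantoms

The phantom generator emulates the *structure* of portal-venous CECT liver
data: an ellipsoidal liver at 100 HU in an air background, hypodense
ellipsoidal lesions (−40 HU offset, optional +30 HU rim), additive Gaussian
noise (15 HU), exact noise-free masks, fully deterministic per seed.  A voxel
belongs to a shape when its centre lies inside.  Lesion centres are sampled
in the inner parallel ellipsoid (semi-axes reduced by the lesion's reach) so
lesions are always intra-hepatic and pairwise disjoint.

`synth_probability_map` stands in for a trained model when testing
post-processing alone: the disease indicator is Gaussian-smoothed and
gamma-sharpened (exponent 1.5).  The gamma term mimics a softmax's confident
interior; it keeps the mid-probability iso-surfaces near the true boundary,
whereas a plain blur places them uniformly outside it (a stronger gamma
over-contracts small, strongly curved lesions).

What the phantom deliberately omits: CT physics (beam hardening, partial
volume, anisotropic noise), vessels and bile ducts, multi-phase contrast
dynamics, irregular lesion shapes, and inter-patient anatomy variation.
Passing the synthetic pipeline therefore demonstrates that the machinery —
normalization, sampling, optimization, growth, metrics — is correct and
integrates end to end; it does not certify clinical accuracy on real CECT.

## The synthetic study

`hepaseg.pipeline.run_synthetic_study` is the end-to-end rehearsal sized for
a single CPU: 20 phantoms (2 lesions each, 14–24 mm) on a 3.0 × 1.6 × 1.6 mm
grid, normalized and resampled to 2.5 × 1.5 × 1.5 mm; 12 × 32 × 32 slabs
from 16 training phantoms; a reduced hybrid W-Net (two-block dense 2D
backbone with growth 4, 4-channel slice features, 4 initial 3D filters,
BN momentum 0.8 so inference statistics converge within the short run)
trained with the full four-phase protocol and per-phase LR finding (12-step
sweeps); predictions grown at (0.67, 0.30) and evaluated on all 20 phantoms
at their original grid.  The whole study runs in a few minutes and reaches a
mean patient Dice well above 0.9 on this easy, high-contrast task.

## Known limitations

- The runtime is CPU-only and sized for phantoms; training the full-scale
  models on real CT cohorts is out of its intended range.
- DICOM series are not read; convert to NIfTI first.
- The 2D decoder of the hybrid is a reconstruction (see *Parameter
  accounting*); published parameter totals are bracketed, not matched.
- The exhaustive (seed, threshold) grid at 0.01 resolution is O(4k pairs ×
  cohort relabelling); tuning large cohorts benefits from the coarser grids
  exposed as arguments.
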