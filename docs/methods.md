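# Methods

This note records the modelling and numerical choices behind `mslesseg`,
in the package's own words: what the pipeline computes, the knobs that
matter, what the synthetic phantoms do and do not emulate, and where the
design was genuinely open.

## Pipeline overview

A 3D multi-modal scan (FLAIR, T1w, T2w on one co-registered grid) is
normalized, sliced along the axial, coronal and sagittal planes, and each
2D slice is resized to 256×256 and segmented independently by a 2D
multi-branch U-Net. The per-slice probability maps of each plane are
inverse-resized to their native shape and restacked into a 3D probability
volume; the three plane volumes are averaged voxelwise and thresholded
last, producing one binary lesion mask. Working in 2D keeps compute low
and multiplies the number of training samples; averaging three orthogonal
views restores part of the through-plane context a 2D model lacks.

## Network

Three encoder branches (one per modality, no weight sharing) of
down-sampling blocks — batch normalization at the block entry, 3×3 ReLU
convolutions each followed by batch normalization, 2×2 max-pooling — with
filter counts n₀·(1, 2, 4, 8) and a 16n₀ bottom block. Pre-pool features
feed multi-modal feature-fusion (MMFF) blocks per resolution level:
concatenation of the three branches' features, normalization, 3×3
convolutions. The decoder starts from the concatenated branch bottoms and
climbs through multi-scale feature-upsampling (MSFU) blocks: 2×
nearest-neighbour upsampling, 3×3 convolution + BN + ReLU, concatenation
with the MMFF output, BN, further 3×3 convolutions. Upsampling layers are
used instead of transposed convolutions, ReLU everywhere except the final
sigmoid, Glorot-normal initialization, no dropout by default (a dropout
rate is exposed but off).

**Parameter-count calibration.** The published description fixes the layer
*kinds* per block but not the number of convolutions inside each block.
The only bit-exact anchor available is the full model's parameter counts
at n₀ = 32: 26,242,733 total = 26,213,223 trainable + 29,510
non-trainable. Since non-trainable parameters are exactly the two moving
statistics per BN channel, the BN channel sum must be 14,755 — which is
odd, implying batch normalization is applied to the three 1-channel
inputs, and large enough that normalization must follow essentially every
stage (convolutions, pools, concatenations). Under that placement, an
exhaustive search over per-block convolution counts
(`scripts/calibrate_recipe.py`) yields 27 recipes matching all three
counts exactly; the committed one — DS blocks (3, 2, 2, 3) convolutions
by level, bottom 2, MMFF (3, 1, 1, 1) and MSFU (3, 1, 2, 2) by decoder
stage — was chosen as the most regular. The recipe reproduces the counts
exactly but is not guaranteed to be the unique graph that does; uniform
per-level recipes provably cannot match.

**Ablation variants.** `no_mmff` replaces each MMFF block with a plain
concatenation; `no_msfu` replaces each MSFU block with convolution →
upsample → concatenation; `neither` does both; `single_input` is a
standard one-encoder U-Net taking the modalities as input channels
(i.e. with weight sharing across modalities). All variants share the full
model's output shape; removing MMFF strictly reduces the parameter count.

## NumPy engine

The network runs on a purpose-built NumPy reverse-mode autodiff engine
(`mslesseg.nn`): 'same'-padded convolution evaluated as one BLAS GEMM per
kernel tap over shifted views, batch normalization with moving statistics,
2×2 max-pooling (gradient split evenly among ties), 2× nearest-neighbour
upsampling, channel concatenation, ReLU, numerically stable sigmoid, Adam,
and an inference mode (`nn.no_grad`) that skips graph construction so
activations are freed eagerly. Gradients of every operation are verified
against central finite differences in the test suite. Float32 throughout.

Numerical constants: BN ε = 10⁻³ and momentum 0.9 (the moving statistics
must track the current weights closely enough to be usable after short
desk-scale trainings; a slower 0.99 momentum leaves eval-mode statistics
stale for hundreds of steps). Dice smoothing s = 1.0; BCE probability
clamp ε = 10⁻⁷; Adam β = (0.9, 0.999), ε = 10⁻⁷.

## Losses

Soft Dice (1 − (2Σpt + s)/(Σp + Σt + s)), binary cross-entropy, their sum
(weights (1, 1) by default — the combination weighting is not specified in
the source description, so an equal-weight sum is used and exposed as a
parameter), and mean-squared error as the weakest baseline. All losses are
evaluated **batch-wise**: the Dice overlap pools every pixel of the batch
rather than averaging per-sample Dice. A regression test asserts the
batch-pooled value differs from the per-sample mean on a constructed
batch, so the implementation cannot silently regress to per-sample
averaging.

## Training

Adam at 3·10⁻⁴ decayed ×0.90 every 300 batches (`lr_at` is the closed
form initial_lr · 0.9^⌊b/300⌋); batch sizes 15/50 (train/validation);
training set reshuffled every epoch and validation set shuffled once;
early stopping with patience 200; checkpoints written every third epoch
*and* at every new validation-loss best. An epoch is one pass over the
selected training slices. Non-finite losses abort training rather than
polluting the selection statistics. Fine-tuning mode (scanner domain
adaptation) reuses the loop with learning rate 10⁻⁵, checkpoints every
fifth epoch, and a 20-epoch budget.

Slice selection keeps every slice with at least one lesion pixel plus
every 30th empty slice, counted 1-based within the ordered empty-slice
subsequence, per volume per plane (the counter's reset scope is not
specified; per-volume-per-plane is the reading implemented). Augmentation
applies one sampled geometric transform (rotation ±15°, shift ±10%, zoom
±10%, horizontal/vertical flips) identically to all modalities and the
label (nearest-neighbour for the label, so it stays binary) plus a
brightness scale ±20% to the images only; ranges are configurable since
only the transform families are prescribed.

## Checkpoint selection

Over the last 150 epochs, every contiguous 50-epoch window is scored by
the *population* variance of its validation losses (the divisor convention
is fixed so the independent oracle matches bit-for-bit). Windows are
visited in ascending variance; within a window, epochs in ascending loss;
the first epoch whose checkpoint exists on disk wins. Ties in variance
break toward the later window and ties in loss toward the later epoch
(more-trained network). If no checkpoint exists anywhere in the span, a
`SelectionError` tells the caller to fall back to the best-loss
checkpoint. The rationale: batch shuffling can produce a lucky low loss
inside an unstable stretch; selecting from the most stable window avoids
such spikes.

## Inference and thresholding

Slices are predicted in batches, inverse-resized bilinearly (probability
space), restacked, averaged across the three planes, and thresholded
last — ties (p = t) count as lesion. The threshold is either fixed
(default 0.5) or chosen by grid search (0.05 steps over (0.05, 0.95))
maximizing mean DSC over validation pairs; a post-hoc threshold scale
factor is exposed (e.g. raising the cut by 10% after fine-tuning).

## Metrics

Voxel metrics use the universal set-overlap definitions (DSC, Jaccard,
PPV, TPR, absolute volume difference relative to ground-truth load).
Lesion-wise rates use 3D connected components — 18-connectivity by
default, configurable to 6 or 26 — with detection defined as ≥1
overlapping voxel and no minimum lesion size. Undefined ratios (empty
ground truth or prediction, no lesions) are reported as NaN sentinels,
never silently substituted, so aggregation choices stay visible. The
composite challenge score is the challenge-canonical weighting
(DSC/8 + PPV/8 + LTPR/4 + (1−LFPR)/4 + volume correlation/4) × 100,
documented as an external convention and overridable; with a single scan
the correlation term is dropped and the weights renormalized, with a
warning. Aggregate reports carry 95% percentile-bootstrap confidence
intervals.

## Phantoms

The generator emulates what the pipeline needs from skull-stripped
challenge data: three co-registered contrasts on a ~1 mm isotropic grid, a
centred brain ellipsoid spanning 70% of each axis over a zero background,
axis-aligned ellipsoidal lesions with radii drawn uniformly from a
configurable range, fixed tissue/lesion means per modality (FLAIR tissue
0.40 / lesion 0.90; T2w 0.45 / 0.85; T1w 0.60 with black-hole lesions at
0.20), additive Gaussian noise, and heavy class imbalance. Defaults:
48³ voxels, 8 lesions of radius 2–5 voxels, 30% black holes, noise SD
0.02. Lesions may overlap unless rejection sampling is requested (used
when a test needs an exact component count). It does **not** emulate MR
physics: no bias fields, partial-volume effects, registration error,
anatomy, or rater disagreement — so passing phantom tests demonstrates
pipeline correctness and learnability, not clinical segmentation accuracy.

A companion generator produces synthetic validation-loss histories
(decreasing / plateau / noisy-spike families) with the trainer's
checkpoint flags, as input for exercising the selection rule.

## Desk-scale test sizes

The learning smoke test trains the n₀ = 4 model on 15 lesion-bearing
slices (the five largest-lesion slices per plane) of one 48³ phantom with
6 lesions of radius 3–6 voxels, batch size 5, for at most 200 epochs with
an early exit once training Dice ≥ 0.9, then segments the phantom through
the full tri-planar path. The learning rate for this narrow model is
3·10⁻³; the published 3·10⁻⁴ is tuned to the 32-filter architecture and
converges an order of magnitude too slowly at 1/64 of the parameter
count. The stochastic criterion is evaluated over up to three seeds
(majority), stopping early once two succeed.

## Known limitations

- Training the full n₀ = 32 model on real challenge data is out of scope
  for a NumPy engine on CPU; the architecture is validated by its exact
  parameter counts and by desk-scale learning, not by leaderboard
  reproduction.
- The calibrated block recipe matches the published parameter counts
  exactly but is one of several graphs that do.
- Bitwise reproducibility is guaranteed for data order, initialization and
  the NumPy compute path on one platform; exact floats may differ across
  BLAS builds.
- The phantom's lesions are smooth ellipsoids; real MS lesions are
  irregular, confluent and rater-dependent.
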