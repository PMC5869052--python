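# Methods

This note documents the models, conventions and numerical choices behind
`voxpipe`, and what the synthetic phantom studies do and do not show.

## Data model and conventions

Volumes are held as 5-axis arrays `(x, y, z, time, channel)` with the
spatial axes exactly as stored in the NIfTI file; coordinates are 0-based
and half-open `[start, end)` throughout. The 4×4 affine maps voxel indices
to world millimetres; spacing is recovered from the affine's column norms
and is used by the distance metrics. A 4-D NIfTI's fourth axis is read as
channels/modalities. Orientation handling is lossless — permutations and
flips only, never resampling — so integer label volumes survive loading,
reorientation and writing bit-for-bit. Subject identifiers are the
filename stem after removing the matched section substring and the NIfTI
extension; ties (two files mapping to one subject/section) are an error
rather than a silent choice.

Label-like sections (`label`, `weight`) are always interpolated
nearest-neighbour and never accept NaNs; image-like sections default to
linear interpolation. This single rule is applied at loading, augmentation
and resize-sampling, which is what guarantees "label output values ⊆
label input values" across the whole pipeline.

## Intensity normalization

Two normalizations are provided and both are optional per run:

* **mean/variance** — per channel, zero mean and unit (population)
  variance; with a mask the statistics come from the mask but the same
  affine map is applied everywhere. Whether to restrict to a foreground
  mask is left to the user; the default uses the whole volume.
* **histogram (landmark) standardization** — percentile ranks
  {1, 5, 10, 20, …, 90, 95, 99} with clipping cutoffs (1, 99) and a fixed
  standard scale that is the ranks mapped onto [0, 100]. Training probes
  each image's (clipped) percentiles, rescales them affinely so the
  endpoints hit the scale, and averages across images per modality.
  *Applying* the model maps a volume's **own** percentile values onto the
  standard scale piecewise-linearly (linear extrapolation beyond the end
  knots). Anchoring the map at the volume's own percentiles is what makes
  the output invariant to affine intensity changes; it also means the
  trained per-modality landmarks act as the dataset's average histogram on
  that scale (and as a record of which modalities were trained) rather
  than as the transform's target knots — a deliberate simplification of
  the classic landmark method, which maps onto the trained means.

The choice matters in practice: per-volume mean/variance normalization
makes the intensity→tissue mapping depend on each subject's tissue volume
fractions. On the calibrated phantom modality (below) this measurably hurt
held-out generalization, so the end-to-end studies train on raw
intensities, the same reasoning that applies to calibrated CT.

## Augmentation

One random affine per training step, composed about the volume centre:
optional per-axis flips (each drawn with probability ½ from the configured
axes), rotations drawn independently per axis from a degree range, and a
single isotropic scale factor drawn as a percentage. Resampling is
pull-back (inverse-transform) interpolation; out-of-field voxels are
filled with the section minimum (images) or 0 (labels). The affine
metadata is not updated — augmented samples exist only inside the training
loop. Defaults when enabled: rotations ±10°, scaling 90–110 %.

## Sampling and aggregation

Training samplers draw windows uniformly over all valid starts, or with
window-centre probability proportional to a nonnegative weight map.
Inference uses a systematic grid: per axis, starts 0, s, 2s, … with stride
`s = window − 2·border`, plus a final start clamped to `dim − window`
(duplicates removed), emitted in lexicographic order. Windows larger than
the volume trigger symmetric edge-replication padding and are flagged; the
grid sampler additionally pads by the border itself so that the central
regions — windows shrunk by the border, which discards convolution edge
effects — can reach the volume edge. The aggregator adds central regions
at `start + border` (minus the recorded padding offset), counts per-voxel
contributions, and finalizes by unweighted averaging (continuous) or by
argmax over summed per-class scores with ties going to the lower class
index. Averaging makes aggregation order-invariant, and the
grid→identity→aggregate round trip is exactly the identity — the module's
central invariant, tested over random geometries.

## Networks and losses

All feature maps are float32 `(batch, channels, x, y, z)` tensors on a
small reverse-mode autodiff core (im2col convolution, instance
normalization, 2× average-pool and trilinear upsampling, matmul,
softmax). Parameters live in a flat `scope/path/name` registry per module;
re-invoking a block under the same scope reuses the same parameters, which
is both the weight-sharing mechanism and the unit of checkpoint transplant
(`restore_checkpoint(..., scope_renames={"net/dfs1": "net2/encoder"})`).

* `conv_block`: stride-1 same-padding convolution → instance norm →
  activation. Instance norm was chosen as the batch-independent
  normalization so batch size never changes behaviour.
* `dense_feature_stack`: block *i* consumes the channel concatenation of
  the stack input and blocks 1…i−1; with input channels C₀ and growth g,
  block *i* sees C₀ + (i−1)·g channels and the stack returns n·g.
* `ReferenceSegNet`: depth-2 V shape — per level a dense stack (2 blocks,
  growth 8) then 2× average-pool; trilinear 2× upsampling on the way up
  with a 3³-convolution skip from each level summed in; a final
  unnormalized 1³ convolution maps to class scores. The raw input is
  concatenated into that final convolution: every trunk path passes
  through window-relative instance norm, so this skip is the only route
  carrying absolute (calibrated) intensity to the classifier — without it
  the phantom task plateaus well below its attainable accuracy. The whole
  model is ~25 k parameters and trains on one CPU in minutes.
* Losses: soft Dice (ε = 1e-5, averaged over all classes including
  background), RMSE (optionally masked), and logit binary cross-entropy.
  The GAN step updates the discriminator on real-vs-generated
  cross-entropy with the generated batch detached, then the generator
  with the non-saturating objective; each phase touches only its own
  optimizer's parameters.
* Optimizer: Adam, default lr 1e-3 (configurable), standard moments.

## Driver, configuration, reproducibility

Runs are described by an INI file (sections `[system] [network] [training]
[inference] [evaluation]` plus one section per data source); parsing fills
every default explicitly, applies CLI overrides, and rejects unknown keys.
Checkpoints are directories holding the parameter archive, the optimizer
state and the fully resolved configuration text, so a checkpoint alone can
recreate the run. One master seed feeds named RNG streams (`sampler`,
`augmentation`, `noise`, `init`), and the training-loop streams are
re-derived per step from (seed, stream, step): a run resumed from step *k*
consumes exactly the draws of an uninterrupted run, which together with
the saved optimizer state makes resumption bitwise identical. Execution is
single-process and sequential by design; outputs are deterministic given
(config, seed, checkpoint).

## Evaluation suite

Surfaces are foreground voxels with at least one six-connected background
neighbour; distances are voxel-centre to voxel-centre, spacing-scaled
(reported in voxels by default, mm on request). The mean absolute,
Hausdorff and 95th-percentile Hausdorff distances are computed on the
pooled bidirectional distance distribution, making all three symmetric;
percentiles use linear interpolation. Region metrics label components by
26-connectivity; a reference component counts as detected on any overlap
(threshold 0⁺, configurable). Compactness is S^1.5/V — the field uses the
name without a fixed formula, so this dimensionally consistent choice is
stated rather than assumed. 0/0 ratios are reported as NaN and kept in the
CSV. Implementations are cross-checked against O(n²) all-pairs oracles in
the test suite.

## Phantoms and what the studies show

The phantom generator rejection-samples non-overlapping ellipsoids (radii
10–25 % of the smallest axis) on a zero background; organ k has constant
mean intensity k (unit separation) plus i.i.d. Gaussian noise, so the
modality is calibrated by construction. Regression pairs share geometry
while the target's per-organ mean is an affine map of the organ *index*,
mimicking MR→CT synthesis where the target is a per-tissue property.
Everything is a pure function of (spec, seed).

The end-to-end studies (`voxpipe.experiments`) use 32³ phantoms with 3
organs and noise 0.1 of the intensity separation, 8 training and 2
held-out subjects, 16³ windows in batches of 4, Adam lr 1e-2, random
affine augmentation, no intensity normalization, 500 (segmentation) or
300 (regression) steps, and grid inference with border 2 — sizes chosen so
each study completes in about two minutes on one CPU. Under these
conditions held-out Dice exceeds 0.9 per organ and held-out voxelwise MAE
is close to the noise floor (≈ noise_sd·√(2/π) if the per-tissue means
were recovered exactly).

What passing shows: the full pipeline — discovery, loading, sampling,
augmentation, optimization, aggregation, evaluation — is wired correctly
and can recover structure whose information content is genuinely present.
What it does not show: performance on real anatomy. The phantoms have
near-separable intensity distributions, no partial-volume effects, no
bias fields, no anisotropic spacing, no inter-subject anatomical
variability; real-data performance is a property of models and datasets
outside this package's scope.

## Known limitations

Single-process CPU execution; no multi-device or queued loading. NIfTI
only (no DICOM/Analyze). No deformable augmentation, intensity-noise
augmentation or bias-field simulation. No cross-validation or
hyper-parameter search orchestration. The autodiff core implements exactly
the operations the included networks need, not a general tensor library.
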