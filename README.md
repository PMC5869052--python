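# voxpipe

Patch-based deep-learning pipelines for volumetric medical images, as a
library plus a thin command-line tool.

Analysing 3-D medical images (CT, MRI, PET …) with convolutional networks
requires a stack of infrastructure that is mostly independent of the model
being studied: finding corresponding image/label files, reading NIfTI
volumes with their spatial metadata, normalizing intensities, augmenting
with random spatial transforms, cutting volumes into fixed-shape windows
for training, sliding a systematic window grid at inference and stitching
the per-window outputs back into whole volumes, and scoring the results
with the field's standard segmentation metrics. `voxpipe` implements that
pipeline end to end for researchers who want to exercise, test or teach
each stage in isolation — every component is importable on its own, and the
whole pipeline runs on synthetically generated phantom volumes, so no
clinical data is needed.

The networks run on a compact reverse-mode autodiff core written on numpy
(`voxpipe.nn.autodiff`): 3-D convolution via im2col, instance
normalization, trilinear up/downsampling and Adam, sized for desk-scale
CPU experiments rather than GPU production runs.

## The core machinery

* **Sampling/aggregation** — training windows are drawn uniformly over
  window starts or with probability proportional to a weight map; at
  inference a grid of windows with stride `window − 2·border` (final
  window clamped to the edge) covers the volume, and the aggregator
  averages the central regions of overlapping windows. For any geometry,
  `grid_sample → identity → aggregate` reproduces the input exactly.
* **Soft Dice loss** — per class *c* with predicted probabilities *p* and
  one-hot reference *g*:
  `d_c = (2 Σ p_c g_c + ε) / (Σ p_c + Σ g_c + ε)`, ε = 1e-5, and
  `loss = 1 − mean_c d_c`. On one-hot predictions `1 − loss` equals the
  mean hard Dice `2|A∩B|/(|A|+|B|)` of the evaluation module.
* **Histogram standardization** — percentile landmarks
  {1, 5, 10, 20, …, 90, 95, 99} are probed per training image, rescaled so
  the endpoints hit a fixed [0, 100] scale, and averaged; applying the
  model maps a volume's own percentiles onto that scale piecewise-linearly,
  which makes the result invariant to affine intensity changes.
* **Evaluation** — Dice/Jaccard/sensitivity/specificity/accuracy from the
  voxel confusion table; mean absolute, Hausdorff and 95th-percentile
  Hausdorff distances on the pooled bidirectional nearest-surface-distance
  distribution (six-connected surfaces, spacing-scaled); region-wise
  detection on 26-connected components; volume and shape descriptors.
* **Networks** — composable blocks under hierarchical named scopes with
  weight sharing, including the dense feature stack (block *i* consumes the
  concatenation of the stack input and all previous block outputs) and a
  small V-shaped reference segmentation network; checkpoints embed the full
  resolved configuration and support scope-renamed restores that transplant
  a named block into a differently named network.

## Worked example

`examples/03_sampling_and_aggregation.py` tiles a 30×26×22 volume with
16³ windows (border 2), pushes each window through an identity network and
reassembles:

```
volume 30x26x22, window 16^3, border 2 -> 18 windows
max |reassembled - input| = 0.0
voxels covered more than once: 9480
```

Eighteen windows cover the volume; 9480 voxels are covered by more than
one central region because the clamped final windows overlap, and the
averaging aggregator still reproduces the input bit-for-bit.

`examples/05_segmentation_metrics.py` scores a 4³ cube against the same
cube shifted by one voxel:

```
confusion: tp=48 fp=16 fn=16 tn=1648
  dice         0.7500
  jaccard      0.6000
  sensitivity  0.7500
  specificity  0.9904
  accuracy     0.9815
  mean_absolute_distance 0.3571 voxels
  hausdorff              1.0000 voxels
  hausdorff95            1.0000 voxels
```

48 of 64 cube voxels still overlap, giving Dice 2·48/128 = 0.75; the
surfaces are at most one voxel apart, so both Hausdorff statistics are 1.

The other examples cover dataset generation/discovery, histogram
standardization, config-driven training + evaluation
(`voxpipe train -c config.ini`, `voxpipe inference …`,
`voxpipe evaluation …`, `voxpipe make-phantoms …` on the command line),
and GAN training with latent-space interpolation.

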