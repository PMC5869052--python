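"""Intensity normalization and random spatial augmentation.

Two image-wide normalizations are provided: zero-mean/unit-variance scaling
and trained histogram (landmark) standardization, in which a set of
percentile landmarks learned over the training set defines a piecewise-linear
intensity remapping.  Spatial augmentation draws a random affine transform
(per-axis flips, per-axis rotations, one isotropic scale) about the volume
centre and resamples every section of a subject with the same transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import (
    DatasetIndex,
    ImageVolume,
    LABEL_LIKE_SECTIONS,
    load_volume,
)

DEFAULT_PERCENTILES = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 95.0, 99.0)
DEFAULT_CUTOFFS = (1.0, 99.0)


class PreprocessingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# mean / variance normalization
# ---------------------------------------------------------------------------

def meanvar_normalize(vol: ImageVolume, mask: np.ndarray | None = None) -> ImageVolume:
    """Scale each channel to zero mean, unit variance (population variance).

    With a mask, the statistics come from voxels inside the mask but the
    same affine map is applied everywhere, so intensities stay comparable
    across the mask boundary.
    """
    data = vol.data.astype(np.float64).copy()
    if mask is not None:
        mask = np.asarray(mask).astype(bool).reshape(vol.spatial_shape)
        if not mask.any():
            raise PreprocessingError("empty normalization mask")
    for ch in range(vol.n_channels):
        channel = data[..., ch]
        sel = channel[mask] if mask is not None else channel
        mu = float(sel.mean())
        sd = float(sel.std())  # ddof=0
        if sd == 0.0:
            raise PreprocessingError(f"zero variance in channel {ch}")
        data[..., ch] = (channel - mu) / sd
    return vol.with_data(data)


# ---------------------------------------------------------------------------
# histogram (landmark) standardization
# ---------------------------------------------------------------------------

@dataclass
class LandmarkModel:
    """Trained percentile landmarks for histogram standardization.

    ``per_modality_landmarks[m][k]`` is the average (over the training set,
    after endpoint rescaling) intensity at ``percentiles[k]`` for modality
    ``m``; ``standard_scale`` is the common target scale those landmarks map
    onto.
    """

    percentiles: np.ndarray
    per_modality_landmarks: dict[str, np.ndarray]
    standard_scale: np.ndarray

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.standard_scale = np.asarray(self.standard_scale, dtype=float)
        if np.any(np.diff(self.percentiles) <= 0):
            raise PreprocessingError("percentile ranks must be strictly increasing")
        for name, lm in self.per_modality_landmarks.items():
            lm = np.asarray(lm, dtype=float)
            if lm.shape != self.percentiles.shape:
                raise PreprocessingError(f"landmark length mismatch for {name!r}")
            if np.any(np.diff(lm) < 0):
                raise PreprocessingError(f"landmarks for {name!r} not nondecreasing")
            self.per_modality_landmarks[name] = lm

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["# percentiles " + " ".join(f"{p:g}" for p in self.percentiles)]
        lines.append("# standard_scale " + " ".join(f"{v:.10g}" for v in self.standard_scale))
        for name, lm in self.per_modality_landmarks.items():
            lines.append(name + " " + " ".join(f"{v:.10g}" for v in lm))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkModel":
        percentiles = standard = None
        landmarks: dict[str, np.ndarray] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            if line.startswith("# percentiles"):
                percentiles = np.array([float(x) for x in line.split()[2:]])
            elif line.startswith("# standard_scale"):
                standard = np.array([float(x) for x in line.split()[2:]])
            else:
                name, *vals = line.split()
                landmarks[name] = np.array([float(x) for x in vals])
        if percentiles is None or standard is None or not landmarks:
            raise PreprocessingError(f"malformed landmark file {path}")
        return cls(percentiles, landmarks, standard)


def _rescaled_percentile_values(
    values: np.ndarray,
    percentiles: np.ndarray,
    cutoffs: tuple[float, float],
    standard_scale: np.ndarray,
) -> np.ndarray:
    """Probe one image's percentiles, clip, and pin endpoints to the scale."""
    finite = values[np.isfinite(values)]
    if np.unique(finite).size < percentiles.size:
        raise PreprocessingError(
            f"too few distinct intensities ({np.unique(finite).size}) "
            f"for {percentiles.size} landmarks"
        )
    low, high = np.percentile(finite, cutoffs)
    clipped = np.clip(finite, low, high)
    probed = np.percentile(clipped, percentiles)
    span = probed[-1] - probed[0]
    if span == 0:
        raise PreprocessingError("degenerate intensity range after clipping")
    # affine map sending the probed endpoints onto the standard-scale endpoints
    return (probed - probed[0]) / span * (standard_scale[-1] - standard_scale[0]) + standard_scale[0]


def train_landmarks(
    index: DatasetIndex,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    section: str = "image",
    standard_scale: Sequence[float] | None = None,
) -> LandmarkModel:
    """Learn per-modality percentile landmarks over a training set.

    Every training image is clipped to its own ``cutoffs`` percentiles, its
    percentile values are affinely rescaled so the endpoints hit the standard
    scale, and the rescaled values are averaged across images.  The default
    standard scale is the percentile ranks themselves mapped onto [0, 100].
    """
    percentiles = np.asarray(percentiles, dtype=float)
    if standard_scale is None:
        p0, p1 = percentiles[0], percentiles[-1]
        standard_scale = (percentiles - p0) / (p1 - p0) * 100.0
    standard_scale = np.asarray(standard_scale, dtype=float)

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for sid in index.subject_ids:
        vol = load_volume(index.subjects[sid][section], index.section_specs[section])
        for ch, name in enumerate(vol.modality_names):
            vals = _rescaled_percentile_values(
                vol.data[..., ch].ravel(), percentiles, cutoffs, standard_scale
            )
            sums[name] = sums.get(name, 0.0) + vals
            counts[name] = counts.get(name, 0) + 1
    landmarks = {name: sums[name] / counts[name] for name in sums}
    return LandmarkModel(percentiles, landmarks, standard_scale)


def histogram_standardize(vol: ImageVolume, model: LandmarkModel) -> ImageVolume:
    """Map a volume's own percentile values onto the trained standard scale.

    Piecewise-linear between landmarks, linearly extrapolated beyond the end
    landmarks; monotone by construction.  Because the mapping is anchored at
    the volume's *own* percentiles, it is invariant to affine intensity
    changes of the input.
    """
    data = vol.data.astype(np.float64).copy()
    for ch, name in enumerate(vol.modality_names):
        if name not in model.per_modality_landmarks:
            raise PreprocessingError(f"no trained landmarks for modality {name!r}")
        channel = data[..., ch]
        finite = channel[np.isfinite(channel)]
        own = np.percentile(finite, model.percentiles)
        target = model.standard_scale
        mapped = np.interp(channel, own, target)
        # linear extrapolation beyond the end landmarks
        if own[1] > own[0]:
            lo = channel < own[0]
            mapped[lo] = target[0] + (channel[lo] - own[0]) * (target[1] - target[0]) / (own[1] - own[0])
        if own[-1] > own[-2]:
            hi = channel > own[-1]
            mapped[hi] = target[-1] + (channel[hi] - own[-1]) * (target[-1] - target[-2]) / (own[-1] - own[-2])
        data[..., ch] = mapped
    return vol.with_data(data)


# ---------------------------------------------------------------------------
# random affine augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationParams:
    """Ranges for the random flip/rotation/scaling augmentation.

    Rotation angles are degrees, drawn independently per spatial axis;
    scaling is a single isotropic percentage (100 = identity).
    """

    flip_axes: tuple[int, ...] = ()
    rotation_range_deg: tuple[float, float] = (0.0, 0.0)
    scaling_range_pct: tuple[float, float] = (100.0, 100.0)

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not (-180.0 <= lo <= hi <= 180.0):
            raise PreprocessingError(f"bad rotation range {self.rotation_range_deg}")
        slo, shi = self.scaling_range_pct
        if not (0.0 < slo <= shi):
            raise PreprocessingError(f"bad scaling range {self.scaling_range_pct}")
        if not set(self.flip_axes) <= {0, 1, 2}:
            raise PreprocessingError(f"bad flip axes {self.flip_axes}")


def _rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    i, j = [a for a in range(3) if a != axis]
    m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
    return m


def sample_affine(params: AugmentationParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one random 4x4 voxel-space transform (flip ∘ rotations ∘ scale).

    The translation part is zero; :func:`apply_transform` centres the
    transform on the volume midpoint.  Deterministic given the generator
    state.
    """
    flips = np.eye(3)
    for ax in sorted(params.flip_axes):
        if rng.random() < 0.5:
            flips[ax, ax] = -1.0
    angles = rng.uniform(*params.rotation_range_deg, size=3) if params.rotation_range_deg != (0.0, 0.0) else np.zeros(3)
    scale = rng.uniform(*params.scaling_range_pct) / 100.0
    rot = np.eye(3)
    for ax in range(3):
        rot = rot @ _rotation_matrix(ax, np.deg2rad(angles[ax]))
    spatial = flips @ rot @ (scale * np.eye(3))
    out = np.eye(4)
    out[:3, :3] = spatial
    return out


def apply_transform(
    vols: Sequence[ImageVolume], transform: np.ndarray
) -> list[ImageVolume]:
    """Resample every section of a subject with one voxel-space transform.

    Pull-back interpolation about the volume centre: image sections use
    linear interpolation with the section minimum as fill, label/weight
    sections use nearest-neighbour with fill 0 so the output label set is a
    subset of the input label set.  The affine metadata is left untouched —
    augmented samples exist only inside the training pipeline.
    """
    transform = np.asarray(transform, dtype=float)
    spatial = transform[:3, :3]
    if abs(np.linalg.det(spatial)) < 1e-12:
        raise PreprocessingError("non-invertible augmentation transform")
    shapes = {v.spatial_shape for v in vols}
    if len(shapes) != 1:
        raise PreprocessingError(f"sections have differing spatial shapes: {shapes}")

    inv = np.linalg.inv(spatial)
    out: list[ImageVolume] = []
    for vol in vols:
        centre = (np.asarray(vol.spatial_shape, dtype=float) - 1.0) / 2.0
        offset = centre - inv @ centre
        is_label = vol.section in LABEL_LIKE_SECTIONS
        order = 0 if is_label else 1
        data = np.empty_like(vol.data, dtype=vol.data.dtype if is_label else np.float64)
        for t in range(vol.data.shape[3]):
            for ch in range(vol.n_channels):
                src = vol.data[:, :, :, t, ch]
                cval = 0 if is_label else float(src.min())
                data[:, :, :, t, ch] = ndimage.affine_transform(
                    src, inv, offset=offset, order=order, mode="constant", cval=cval
                )
        out.append(vol.with_data(data))
    return out
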