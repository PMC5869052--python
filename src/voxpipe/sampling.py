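"""Window samplers: volumes in, a stream of fixed-shape windows out.

Training uses random samplers (uniform over window starts, or weighted by a
per-voxel map); inference uses the systematic grid sampler whose windows,
shrunk by a border, cover the whole volume, or the resize sampler which
rescales the whole volume to a fixed shape.  A noise sampler provides the
latent vectors for generative models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume, LABEL_LIKE_SECTIONS


class SamplingError(RuntimeError):
    pass


@dataclass
class SampleWindow:
    """One packet of corresponding per-section arrays plus its placement.

    ``start`` is the 0-based inclusive corner in the (possibly padded)
    volume; ``placement_valid`` is False when the window only fits because
    the volume was padded.  ``original_shape`` records the unpadded volume
    shape so aggregation can crop back.
    """

    subject_id: str
    start: tuple[int, int, int]
    shape: tuple[int, int, int]
    arrays: dict[str, np.ndarray]
    placement_valid: bool = True
    original_shape: tuple[int, int, int] | None = None
    #: low-side padding applied before sampling (border + undersize padding);
    #: ``start`` is expressed on the padded grid
    padding_offset: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise SamplingError(f"non-positive window shape {self.shape}")
        for name, arr in self.arrays.items():
            if tuple(arr.shape[:3]) != tuple(self.shape):
                raise SamplingError(
                    f"section {name!r} array shape {arr.shape[:3]} != window {self.shape}"
                )


@dataclass
class NoiseSample:
    """One latent vector drawn from an isotropic Gaussian."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise SamplingError("non-finite noise sample")


def _as_shape3(shape) -> tuple[int, int, int]:
    s = tuple(int(x) for x in np.atleast_1d(shape))
    if len(s) == 1:
        s = s * 3
    if len(s) != 3:
        raise SamplingError(f"expected 3 spatial dims, got {shape}")
    return s


def _pad_to_fit(
    vols: Mapping[str, ImageVolume], window: tuple[int, int, int]
) -> tuple[dict[str, np.ndarray], tuple[int, int, int], bool]:
    """Edge-replicate-pad all sections symmetrically so the window fits."""
    vol_shape = next(iter(vols.values())).spatial_shape
    pads = []
    needed = False
    for dim, win in zip(vol_shape, window):
        short = max(0, win - dim)
        lo = short // 2
        pads.append((lo, short - lo))
        needed = needed or short > 0
    arrays = {}
    for name, vol in vols.items():
        arr = vol.data
        if needed:
            arr = np.pad(arr, pads + [(0, 0), (0, 0)], mode="edge")
        arrays[name] = arr
    padded_shape = tuple(d + lo + hi for d, (lo, hi) in zip(vol_shape, pads))
    return arrays, padded_shape, needed


def _crop(arrays: Mapping[str, np.ndarray], start, shape) -> dict[str, np.ndarray]:
    sl = tuple(slice(s, s + w) for s, w in zip(start, shape))
    return {name: arr[sl] for name, arr in arrays.items()}


def uniform_sample(
    vols: Mapping[str, ImageVolume],
    window_shape,
    n: int,
    rng: np.random.Generator,
    subject_id: str = "",
    allow_padding: bool = True,
) -> Iterator[SampleWindow]:
    """Draw ``n`` windows with starts uniform over all valid positions.

    All sections of the subject are cropped with the same start/shape, so
    image, label and weight arrays stay in voxel correspondence.
    """
    window = _as_shape3(window_shape)
    vol_shape = next(iter(vols.values())).spatial_shape
    if any(w > d for w, d in zip(window, vol_shape)) and not allow_padding:
        raise SamplingError(f"window {window} larger than volume {vol_shape}")
    arrays, padded_shape, padded = _pad_to_fit(vols, window)
    n_positions = [d - w + 1 for d, w in zip(padded_shape, window)]
    for _ in range(int(n)):
        start = tuple(int(rng.integers(0, p)) for p in n_positions)
        yield SampleWindow(
            subject_id=subject_id,
            start=start,
            shape=window,
            arrays=_crop(arrays, start, window),
            placement_valid=not padded,
            original_shape=vol_shape,
        )


def weighted_sample(
    vols: Mapping[str, ImageVolume],
    window_shape,
    weight_section: str,
    n: int,
    rng: np.random.Generator,
    subject_id: str = "",
) -> Iterator[SampleWindow]:
    """Draw windows whose *centre* voxel is picked ∝ the weight map.

    Only centres whose window fits inside the (padded) volume are eligible;
    an all-zero eligible weight region is an error.
    """
    window = _as_shape3(window_shape)
    if weight_section not in vols:
        raise SamplingError(f"no section {weight_section!r} to weight by")
    arrays, padded_shape, padded = _pad_to_fit(vols, window)
    vol_shape = next(iter(vols.values())).spatial_shape

    weights = arrays[weight_section][..., 0, 0].astype(np.float64)
    if np.any(weights < 0):
        raise SamplingError("negative weights")
    # a window with start s covers centre c = s + window//2
    half = [w // 2 for w in window]
    valid = np.zeros_like(weights, dtype=bool)
    sl = tuple(
        slice(h, h + (d - w + 1)) for h, d, w in zip(half, padded_shape, window)
    )
    valid[sl] = True
    weights = np.where(valid, weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise SamplingError("all-zero weights over valid window centres")
    flat = weights.ravel() / total
    choices = rng.choice(flat.size, size=int(n), p=flat)
    for idx in choices:
        centre = np.unravel_index(int(idx), weights.shape)
        start = tuple(int(c - h) for c, h in zip(centre, half))
        yield SampleWindow(
            subject_id=subject_id,
            start=start,
            shape=window,
            arrays=_crop(arrays, start, window),
            placement_valid=not padded,
            original_shape=vol_shape,
        )


def _grid_starts(dim: int, window: int, border: int) -> list[int]:
    stride = window - 2 * border
    if stride <= 0:
        raise SamplingError(
            f"window {window} must be >= 2*border+1 (border {border})"
        )
    starts = list(range(0, max(dim - window, 0) + 1, stride))
    if starts[-1] + window < dim:
        starts.append(dim - window)  # clamped final window
    # dedupe while preserving order (clamp may duplicate the last start)
    seen: set[int] = set()
    return [s for s in starts if not (s in seen or seen.add(s))]


def grid_sample(
    vols: Mapping[str, ImageVolume],
    window_shape,
    border=0,
    subject_id: str = "",
) -> list[SampleWindow]:
    """Systematic tiling: windows whose central regions cover the volume.

    Per axis the starts are ``0, s, 2s, ...`` with stride
    ``s = window - 2*border`` plus a final start clamped to ``dim - window``;
    windows are emitted in lexicographic (x, y, z) order.  Undersized volumes
    are symmetrically edge-padded and flagged ``placement_valid=False``.
    """
    window = _as_shape3(window_shape)
    border3 = _as_shape3(border) if not np.isscalar(border) else (int(border),) * 3
    vol_shape = next(iter(vols.values())).spatial_shape
    for w, b in zip(window, border3):
        if w < 2 * b + 1:
            raise SamplingError(f"window {window} must be >= 2*border+1 (border {border3})")

    # pad by the border (so central regions can reach the volume edge), then
    # symmetrically for undersized volumes
    base = {
        name: np.pad(
            vol.data, [(b, b) for b in border3] + [(0, 0), (0, 0)], mode="edge"
        ) if any(border3) else vol.data
        for name, vol in vols.items()
    }
    bordered_shape = tuple(d + 2 * b for d, b in zip(vol_shape, border3))
    pads, undersized = [], False
    for dim, win in zip(bordered_shape, window):
        short = max(0, win - dim)
        lo = short // 2
        pads.append((lo, short - lo))
        undersized = undersized or short > 0
    if undersized:
        base = {
            name: np.pad(arr, pads + [(0, 0), (0, 0)], mode="edge")
            for name, arr in base.items()
        }
    padded_shape = tuple(d + lo + hi for d, (lo, hi) in zip(bordered_shape, pads))
    offset = tuple(b + lo for b, (lo, _) in zip(border3, pads))

    axes_starts = [
        _grid_starts(d, w, b) for d, w, b in zip(padded_shape, window, border3)
    ]
    out = []
    for sx in axes_starts[0]:
        for sy in axes_starts[1]:
            for sz in axes_starts[2]:
                start = (sx, sy, sz)
                out.append(
                    SampleWindow(
                        subject_id=subject_id,
                        start=start,
                        shape=window,
                        arrays=_crop(base, start, window),
                        placement_valid=not undersized,
                        original_shape=vol_shape,
                        padding_offset=offset,
                    )
                )
    return out


def _zoom_section(arr: np.ndarray, target: tuple[int, int, int], order: int) -> np.ndarray:
    """Rescale the spatial axes of a 5-axis array to ``target``."""
    factors = [t / s for t, s in zip(target, arr.shape[:3])] + [1.0, 1.0]
    return ndimage.zoom(arr, factors, order=order, mode="nearest", grid_mode=True)


def resize_sample(
    vols: Mapping[str, ImageVolume], target_shape, subject_id: str = ""
) -> SampleWindow:
    """Rescale whole volumes to a fixed shape (linear image, nearest label)."""
    target = _as_shape3(target_shape)
    vol_shape = next(iter(vols.values())).spatial_shape
    arrays = {}
    for name, vol in vols.items():
        order = 0 if vol.section in LABEL_LIKE_SECTIONS else 1
        if target == vol.spatial_shape:
            arrays[name] = vol.data.copy()
        else:
            arrays[name] = _zoom_section(vol.data, target, order)
    return SampleWindow(
        subject_id=subject_id,
        start=(0, 0, 0),
        shape=target,
        arrays=arrays,
        placement_valid=(target == vol_shape),
        original_shape=vol_shape,
    )


def sample_noise(
    dim: int, n: int, rng: np.random.Generator
) -> list[NoiseSample]:
    """Draw ``n`` i.i.d. standard-normal latent vectors of length ``dim``."""
    if dim < 1:
        raise SamplingError(f"noise dimension must be >= 1, got {dim}")
    return [NoiseSample(vector=rng.standard_normal(int(dim))) for _ in range(int(n))]
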