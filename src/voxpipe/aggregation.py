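"""Recombining per-window network outputs into whole-volume results.

The grid aggregator is the inverse of the grid sampler: each window's
central region (the window shrunk by the border, which discards convolution
edge effects) is added into an accumulator, overlaps are resolved by
unweighted averaging (continuous outputs) or summed-score argmax (labels),
and finalization requires every voxel to have been covered at least once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sampling import SampleWindow, _as_shape3, _zoom_section
from .volume_io import ImageVolume


class AggregationError(RuntimeError):
    pass


@dataclass
class AggregationState:
    """Running accumulators for grid aggregation."""

    output: np.ndarray  # (x, y, z, channels) float
    weight: np.ndarray  # (x, y, z) int, contributions per voxel
    original_shape: tuple[int, int, int]
    border: tuple[int, int, int]
    padding_offset: tuple[int, int, int] = (0, 0, 0)
    finalized: bool = False


def init_grid_aggregation(
    original_shape, channels: int, border=0, padding_offset=(0, 0, 0)
) -> AggregationState:
    """Zeroed accumulators for a volume of ``original_shape``.

    ``padding_offset`` is the low-side padding the grid sampler applied
    (it is recorded on every :class:`~voxpipe.sampling.SampleWindow`); it
    maps window starts from the padded grid back to the original one.
    """
    shape = _as_shape3(original_shape)
    if min(shape) <= 0 or channels <= 0:
        raise AggregationError(f"non-positive accumulator shape {shape} x {channels}")
    border3 = _as_shape3(border) if not np.isscalar(border) else (int(border),) * 3
    offset = tuple(int(o) for o in padding_offset)
    return AggregationState(
        output=np.zeros(shape + (int(channels),), dtype=np.float64),
        weight=np.zeros(shape, dtype=np.int64),
        original_shape=shape,
        border=border3,
        padding_offset=offset,
    )


def accumulate_window(
    state: AggregationState, window: SampleWindow, output_array: np.ndarray
) -> AggregationState:
    """Add one window's central region into the accumulator.

    ``output_array`` is (wx, wy, wz, channels) or (wx, wy, wz).  The region
    is placed at ``start + border`` in padded coordinates; parts outside the
    original volume (possible only for padded volumes) are cropped away.
    """
    if state.finalized:
        raise AggregationError("cannot accumulate into a finalized state")
    out = np.asarray(output_array, dtype=np.float64)
    if out.ndim == 3:
        out = out[..., np.newaxis]
    if tuple(out.shape[:3]) != tuple(window.shape):
        raise AggregationError(
            f"output spatial shape {out.shape[:3]} != window shape {window.shape}"
        )
    if out.shape[3] != state.output.shape[3]:
        raise AggregationError(
            f"output has {out.shape[3]} channels, accumulator {state.output.shape[3]}"
        )

    dst_sl, src_sl = [], []
    for ax in range(3):
        b = state.border[ax]
        # central region in padded coordinates, then shift to original grid
        lo = window.start[ax] + b - state.padding_offset[ax]
        hi = window.start[ax] + window.shape[ax] - b - state.padding_offset[ax]
        crop_lo = max(lo, 0)
        crop_hi = min(hi, state.original_shape[ax])
        if crop_lo >= crop_hi:
            raise AggregationError(
                f"window at {window.start} contributes nothing on axis {ax}"
            )
        dst_sl.append(slice(crop_lo, crop_hi))
        src_sl.append(slice(b + (crop_lo - lo), b + (crop_lo - lo) + (crop_hi - crop_lo)))
    state.output[tuple(dst_sl)] += out[tuple(src_sl)]
    state.weight[tuple(dst_sl)] += 1
    return state


def finalize_aggregation(
    state: AggregationState,
    output_kind: str = "continuous",
    reference: ImageVolume | None = None,
) -> ImageVolume:
    """Resolve overlaps and return the whole-volume output.

    Continuous outputs are divided by the per-voxel contribution count;
    label outputs are the argmax over summed per-class score channels, ties
    broken toward the lower class index (numpy argmax convention).
    """
    if np.any(state.weight == 0):
        n = int(np.count_nonzero(state.weight == 0))
        raise AggregationError(f"incomplete coverage: {n} voxels never accumulated")
    state.finalized = True
    if output_kind == "label":
        data = np.argmax(state.output, axis=3).astype(np.int32)
    elif output_kind == "continuous":
        data = state.output / state.weight[..., np.newaxis]
        if data.shape[3] == 1:
            data = data[..., 0]
    else:
        raise AggregationError(f"unknown output kind {output_kind!r}")
    affine = reference.affine if reference is not None else np.eye(4)
    section = "label" if output_kind == "label" else "inferred"
    n_ch = 1 if data.ndim == 3 else data.shape[3]
    return ImageVolume(
        data=data,
        affine=affine,
        section=section,
        modality_names=[f"out{i}" for i in range(n_ch)],
    )


def resize_aggregate(
    window: SampleWindow,
    output_array: np.ndarray,
    output_kind: str = "continuous",
    reference: ImageVolume | None = None,
) -> ImageVolume:
    """Inverse of the resize sampler: rescale the output back to the
    original volume shape (nearest for labels, linear for continuous)."""
    if window.original_shape is None:
        raise AggregationError("window carries no original_shape record")
    out = np.asarray(output_array, dtype=np.float64)
    if out.ndim == 3:
        out = out[..., np.newaxis]
    if output_kind == "label":
        if out.shape[3] > 1:
            out = np.argmax(out, axis=3)[..., np.newaxis].astype(np.int32)
        order = 0
    else:
        order = 1
    arr5 = out[:, :, :, np.newaxis, :]  # (x, y, z, 1, c)
    target = tuple(window.original_shape)
    if tuple(arr5.shape[:3]) != target:
        arr5 = _zoom_section(arr5, target, order)
    if output_kind == "label":
        arr5 = np.round(arr5).astype(np.int32)
    affine = reference.affine if reference is not None else np.eye(4)
    section = "label" if output_kind == "label" else "inferred"
    return ImageVolume(
        data=arr5,
        affine=affine,
        section=section,
        modality_names=[f"out{i}" for i in range(arr5.shape[4])],
    )
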