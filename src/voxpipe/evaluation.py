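"""Segmentation evaluation: overlap, volume, surface-distance, region-wise
and descriptive metrics, reported per subject and per label as a tidy table.

Conventions chosen for determinism:

* surfaces are foreground voxels with at least one six-connected background
  neighbour; distances are voxel-centre to voxel-centre, scaled by spacing;
* the mean absolute distance, Hausdorff and 95th-percentile Hausdorff are
  computed on the *pooled* bidirectional distance distribution (so all three
  are symmetric in their arguments); percentiles use linear interpolation;
* 0/0 ratios are reported as NaN and kept in the output, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import DatasetIndex, ImageVolume, load_volume


class EvaluationError(RuntimeError):
    pass


OVERLAP_METRICS = ("dice", "jaccard", "sensitivity", "specificity", "accuracy")
DISTANCE_METRICS = ("mean_absolute_distance", "hausdorff", "hausdorff95")
VOLUME_METRICS = ("volume_mm3", "relative_volume_difference")
REGION_METRICS = ("detection_rate", "region_sensitivity",
                  "region_specificity", "region_accuracy")
DEFAULT_METRICS = OVERLAP_METRICS + VOLUME_METRICS + DISTANCE_METRICS


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(arr: np.ndarray, label_value: int) -> np.ndarray:
    return np.squeeze(np.asarray(arr)) == label_value


def confusion_counts(seg, ref, label_value: int) -> ConfusionCounts:
    """Voxel-wise confusion counts of the masks binarized at ``label_value``."""
    s = _as_binary(seg, label_value)
    r = _as_binary(ref, label_value)
    if s.shape != r.shape:
        raise EvaluationError(f"shape mismatch: seg {s.shape} vs ref {r.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(s & r)),
        fp=int(np.count_nonzero(s & ~r)),
        tn=int(np.count_nonzero(~s & ~r)),
        fn=int(np.count_nonzero(~s & r)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def overlap_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "jaccard": _ratio(c.tp, c.tp + c.fp + c.fn),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


def volume_metrics(seg, ref, spacing: Sequence[float], label_value: int = 1) -> dict[str, float]:
    """Foreground volume in mm^3 and the relative volume difference
    ``|V_seg − V_ref| / V_ref``."""
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise EvaluationError(f"non-positive spacing {spacing}")
    voxel = float(np.prod(spacing))
    v_seg = int(np.count_nonzero(_as_binary(seg, label_value))) * voxel
    v_ref = int(np.count_nonzero(_as_binary(ref, label_value))) * voxel
    return {
        "volume_mm3": v_seg,
        "relative_volume_difference": _ratio(abs(v_seg - v_ref), v_ref),
    }


_FACE_NEIGHBOURS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 six-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACE_NEIGHBOURS, border_value=0)
    return mask & ~eroded


def surface_distances(seg, ref, spacing=(1.0, 1.0, 1.0), label_value: int = 1) -> dict[str, float]:
    """Pooled bidirectional surface distances between two masks.

    For each surface voxel of one mask, the Euclidean distance (spacing-
    scaled) to the nearest surface voxel of the other; the pooled values of
    both directions give the mean absolute distance, the Hausdorff distance
    (their maximum), and the 95th-percentile Hausdorff.
    """
    s = _as_binary(seg, label_value)
    r = _as_binary(ref, label_value)
    if s.shape != r.shape:
        raise EvaluationError(f"shape mismatch: seg {s.shape} vs ref {r.shape}")
    nan = {m: float("nan") for m in DISTANCE_METRICS}
    if not s.any() or not r.any():
        return nan
    spacing = np.asarray(spacing, dtype=float)
    pts_s = np.argwhere(surface_voxels(s)) * spacing
    pts_r = np.argwhere(surface_voxels(r)) * spacing
    d_sr = cKDTree(pts_r).query(pts_s)[0]
    d_rs = cKDTree(pts_s).query(pts_r)[0]
    pooled = np.concatenate([d_sr, d_rs])
    return {
        "mean_absolute_distance": float(pooled.mean()),
        "hausdorff": float(pooled.max()),
        "hausdorff95": float(np.percentile(pooled, 95)),  # linear interpolation
    }


_COMPONENT_STRUCTURE = ndimage.generate_binary_structure(3, 3)  # 26-connectivity


def region_metrics(seg, ref, overlap_fraction_threshold: float = 0.0,
                   label_value: int = 1) -> dict[str, float]:
    """Region-wise detection statistics on 26-connected components.

    A reference component is *detected* when the fraction of its voxels
    covered by the segmentation reaches the threshold (a threshold of 0
    means any overlap of at least one voxel counts); a segmentation
    component overlapping no reference component is a region false
    positive.
    """
    s = _as_binary(seg, label_value)
    r = _as_binary(ref, label_value)
    if s.shape != r.shape:
        raise EvaluationError(f"shape mismatch: seg {s.shape} vs ref {r.shape}")
    ref_lab, n_ref = ndimage.label(r, structure=_COMPONENT_STRUCTURE)
    seg_lab, n_seg = ndimage.label(s, structure=_COMPONENT_STRUCTURE)

    detected = 0
    for i in range(1, n_ref + 1):
        comp = ref_lab == i
        frac = np.count_nonzero(comp & s) / np.count_nonzero(comp)
        hit = frac > 0.0 if overlap_fraction_threshold == 0.0 \
            else frac >= overlap_fraction_threshold
        if hit:
            detected += 1
    region_fps = sum(
        1 for j in range(1, n_seg + 1)
        if not np.count_nonzero((seg_lab == j) & r)
    )
    detection_rate = _ratio(detected, n_ref)
    return {
        "detection_rate": detection_rate,
        "region_sensitivity": detection_rate,
        "region_specificity": 1.0 - _ratio(region_fps, n_seg) if n_seg else float("nan"),
        "region_accuracy": _ratio(detected + (n_seg - region_fps), n_ref + n_seg),
    }


def descriptive_stats(seg, image, spacing=(1.0, 1.0, 1.0), label_value: int = 1) -> dict[str, float]:
    """Shape and intensity descriptors of one labelled region.

    Surface area counts six-connected foreground/background face
    transitions times the face area; compactness is ``S^1.5 / V``;
    intensity statistics are taken over voxels inside the mask, with
    skewness from the central-moment formula ``m3 / m2^1.5``.
    """
    mask = _as_binary(seg, label_value)
    if not mask.any():
        raise EvaluationError(f"empty mask for label {label_value}")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    volume = np.count_nonzero(mask) * voxel_volume

    face_areas = [
        float(spacing[1] * spacing[2]),
        float(spacing[0] * spacing[2]),
        float(spacing[0] * spacing[1]),
    ]
    surface = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        transitions = np.count_nonzero(np.diff(padded.astype(np.int8), axis=axis))
        surface += transitions * area

    vals = np.squeeze(np.asarray(image))[mask].astype(np.float64)
    m = vals.mean()
    m2 = ((vals - m) ** 2).mean()
    m3 = ((vals - m) ** 3).mean()
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return {
        "volume_mm3": volume,
        "surface_mm2": surface,
        "surface_volume_ratio": surface / volume,
        "compactness": surface ** 1.5 / volume,
        "intensity_mean": float(m),
        "intensity_q25": float(q25),
        "intensity_median": float(q50),
        "intensity_q75": float(q75),
        "intensity_skewness": float(skew),
    }


def _metrics_for_pair(
    seg: np.ndarray, ref: np.ndarray, spacing, label: int, metrics: Sequence[str],
    distance_units: str = "voxels",
) -> dict[str, float]:
    out: dict[str, float] = {}
    wanted = set(metrics)
    if wanted & set(OVERLAP_METRICS):
        om = overlap_metrics(confusion_counts(seg, ref, label))
        out.update({k: v for k, v in om.items() if k in wanted})
    if wanted & set(VOLUME_METRICS):
        vm = volume_metrics(seg, ref, spacing, label)
        out.update({k: v for k, v in vm.items() if k in wanted})
    if wanted & set(DISTANCE_METRICS):
        sp = (1.0, 1.0, 1.0) if distance_units == "voxels" else spacing
        dm = surface_distances(seg, ref, sp, label)
        out.update({k: v for k, v in dm.items() if k in wanted})
    if wanted & set(REGION_METRICS):
        rm = region_metrics(seg, ref, label_value=label)
        out.update({k: v for k, v in rm.items() if k in wanted})
    return out


def evaluate_subjects(
    index: DatasetIndex,
    seg_dir: str | Path,
    metrics: Sequence[str] = DEFAULT_METRICS,
    labels: Sequence[int] | None = None,
    ref_section: str = "label",
    seg_suffix: str = "_niftynet_out.nii.gz",
    distance_units: str = "voxels",
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate one inferred segmentation per subject against its reference.

    Returns a tidy frame with columns (subject_id, label, metric, value);
    an aggregate pseudo-subject ``"median"`` holds the per-metric median
    over subjects.  Distances are reported in voxels by default (set
    ``distance_units="mm"`` for spacing-scaled values).
    """
    seg_dir = Path(seg_dir)
    rows: list[tuple[str, int, str, float]] = []
    for sid in index.subject_ids:
        seg_path = seg_dir / f"{sid}{seg_suffix}"
        if not seg_path.exists():
            raise EvaluationError(f"missing segmentation for subject {sid!r}: {seg_path}")
        seg_vol = load_volume(seg_path, index.section_specs.get(ref_section))
        ref_vol = load_volume(index.subjects[sid][ref_section],
                              index.section_specs.get(ref_section))
        seg = np.squeeze(seg_vol.data)
        ref = np.squeeze(ref_vol.data)
        subject_labels = labels
        if subject_labels is None:
            subject_labels = sorted(int(v) for v in np.unique(ref) if v != 0)
        for label in subject_labels:
            vals = _metrics_for_pair(seg, ref, ref_vol.spacing, label, metrics,
                                     distance_units)
            for metric in metrics:
                if metric in vals:
                    rows.append((sid, label, metric, float(vals[metric])))

    report = pd.DataFrame(rows, columns=["subject_id", "label", "metric", "value"])
    medians = (
        report.groupby(["label", "metric"], sort=False)["value"]
        .median()
        .reset_index()
    )
    medians.insert(0, "subject_id", "median")
    report = pd.concat([report, medians], ignore_index=True)
    if csv_path is not None:
        report.to_csv(csv_path, index=False)
    return report
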