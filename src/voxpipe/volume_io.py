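"""Dataset discovery and NIfTI volume input/output.

A dataset is a collection of *subjects*, each contributing one file per
*section* (``image``, ``label``, ``weight`` ...).  Subjects are found either
by matching filename substrings under a search directory or through an
explicit CSV manifest.  Volumes are held in a fixed 5-axis layout
``(x, y, z, time, channel)`` together with their spatial metadata, so that
every later pipeline stage can rely on one convention.

Coordinates are 0-based and half-open ``[start, end)``; the spatial axes are
ordered ``(x, y, z)`` exactly as stored in the NIfTI array.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

NIFTI_EXTENSIONS = (".nii.gz", ".nii")

#: sections whose voxel values are categorical and must never be interpolated
LABEL_LIKE_SECTIONS = frozenset({"label", "weight"})


class VolumeIOError(RuntimeError):
    """Raised for dataset-discovery and volume input/output failures."""


@dataclass
class SectionSpec:
    """Per-section loading rules.

    interp_order 0 means nearest-neighbour (labels, weights); 1 means
    linear (images).  ``n_channels`` of ``None`` accepts whatever the file
    provides.
    """

    name: str = "image"
    interp_order: int = 1
    n_channels: int | None = None

    @classmethod
    def for_section(cls, name: str) -> "SectionSpec":
        order = 0 if name in LABEL_LIKE_SECTIONS else 1
        return cls(name=name, interp_order=order)


@dataclass
class ImageVolume:
    """A voxel array plus the spatial metadata needed to interpret it.

    ``data`` always has 5 axes ``(x, y, z, time, channel)`` with singleton
    axes allowed; ``affine`` maps voxel indices to world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray
    section: str = "image"
    modality_names: Sequence[str] = field(default_factory=lambda: ["modality0"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            self.data = _to_5d(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeIOError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeIOError("affine is not invertible")
        if min(self.spatial_shape) < 1:
            raise VolumeIOError(f"spatial dims must be >= 1, got {self.spatial_shape}")
        if len(self.modality_names) != self.data.shape[4]:
            raise VolumeIOError(
                f"{self.data.shape[4]} channels but "
                f"{len(self.modality_names)} modality names"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_channels(self) -> int:
        return self.data.shape[4]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel size in mm along each spatial axis (column norms of the affine)."""
        sp = tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))
        if min(sp) <= 0:
            raise VolumeIOError(f"non-positive spacing {sp}")
        return sp

    @property
    def axcodes(self) -> tuple[str, str, str]:
        """Anatomical orientation codes, e.g. ('R', 'A', 'S')."""
        return tuple(nib.orientations.aff2axcodes(self.affine))

    def with_data(self, data: np.ndarray, **kwargs) -> "ImageVolume":
        return replace(self, data=_to_5d(np.asarray(data)), **kwargs)


def _to_5d(arr: np.ndarray) -> np.ndarray:
    if arr.ndim > 5:
        raise VolumeIOError(f"cannot interpret {arr.ndim}-D array as a volume")
    if arr.ndim == 4:
        # a 4th axis is taken as channels/modalities; time stays singleton
        arr = arr[:, :, :, np.newaxis, :]
    while arr.ndim < 5:
        arr = arr[..., np.newaxis]
    return arr


@dataclass
class DatasetIndex:
    """Ordered subject -> {section -> file path} table."""

    subjects: dict[str, dict[str, Path]]
    section_specs: dict[str, SectionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sections = None
        for sid, secs in self.subjects.items():
            names = tuple(sorted(secs))
            if sections is None:
                sections = names
            elif names != sections:
                raise VolumeIOError(
                    f"subject {sid!r} has sections {names}, expected {sections}"
                )
        for name in sections or ():
            self.section_specs.setdefault(name, SectionSpec.for_section(name))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def section_names(self) -> list[str]:
        first = next(iter(self.subjects.values()), {})
        return list(first)

    def __len__(self) -> int:
        return len(self.subjects)


def _strip_nifti_ext(name: str) -> str:
    for ext in NIFTI_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return name


def discover_dataset(
    search_path: str | Path,
    section_patterns: Mapping[str, Sequence[str]],
) -> DatasetIndex:
    """Find corresponding files by filename-substring matching.

    Each section is described by one or more substrings; a file belongs to a
    section when its name contains any of them.  The subject id is the
    filename stem with the matched substring and the NIfTI extension removed.
    Subjects missing any section are excluded (and logged); two files
    resolving to the same (subject, section) raise an ambiguity error.
    """
    search_path = Path(search_path)
    if not search_path.is_dir():
        raise VolumeIOError(f"search path does not exist: {search_path}")
    if not section_patterns:
        raise VolumeIOError("at least one section pattern is required")

    found: dict[str, dict[str, Path]] = {}
    for path in sorted(search_path.rglob("*")):
        if not path.is_file() or not path.name.endswith(NIFTI_EXTENSIONS):
            continue
        stem = _strip_nifti_ext(path.name)
        for section, patterns in section_patterns.items():
            for pat in patterns:
                if pat in stem:
                    sid = stem.replace(pat, "", 1)
                    prev = found.setdefault(sid, {}).get(section)
                    if prev is not None and prev != path:
                        raise VolumeIOError(
                            f"ambiguous files for subject {sid!r} section "
                            f"{section!r}: {prev} and {path}"
                        )
                    found[sid][section] = path
                    break

    wanted = set(section_patterns)
    complete = {
        sid: secs for sid, secs in sorted(found.items()) if set(secs) == wanted
    }
    for sid, secs in sorted(found.items()):
        if set(secs) != wanted:
            missing = sorted(wanted - set(secs))
            logger.warning("subject %r incomplete: missing sections %s", sid, missing)
    if not complete:
        raise VolumeIOError(
            f"zero complete subjects found in {search_path} "
            f"for sections {sorted(wanted)}"
        )
    return DatasetIndex(subjects=complete)


def load_manifest(csv_path: str | Path) -> DatasetIndex:
    """Read an explicit subject table: header ``subject_id,<section>,...``.

    Relative paths are resolved against the CSV's own directory; rows become
    subjects in file order.
    """
    csv_path = Path(csv_path)
    base = csv_path.parent
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "subject_id" not in reader.fieldnames:
            raise VolumeIOError(f"{csv_path}: header must include 'subject_id'")
        sections = [c for c in reader.fieldnames if c != "subject_id"]
        if not sections:
            raise VolumeIOError(f"{csv_path}: no section columns in header")
        subjects: dict[str, dict[str, Path]] = {}
        for row in reader:
            sid = row["subject_id"]
            if sid in subjects:
                raise VolumeIOError(f"{csv_path}: duplicate subject_id {sid!r}")
            entry = {}
            for sec in sections:
                p = Path(row[sec])
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise VolumeIOError(
                        f"{csv_path}: file not found for {sid},{sec}: {p}"
                    )
                entry[sec] = p
            subjects[sid] = entry
    if not subjects:
        raise VolumeIOError(f"{csv_path}: zero subjects")
    return DatasetIndex(subjects=subjects)


def load_volume(path: str | Path, section_spec: SectionSpec | None = None) -> ImageVolume:
    """Load a NIfTI file into the 5-axis layout, preserving metadata.

    Integer label volumes are loaded losslessly; NaN voxels in a label-like
    section are rejected because they cannot represent a class.
    """
    path = Path(path)
    spec = section_spec or SectionSpec()
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    arr = _to_5d(np.asanyarray(img.dataobj))
    if spec.name in LABEL_LIKE_SECTIONS and np.issubdtype(arr.dtype, np.floating):
        if np.isnan(arr).any():
            raise VolumeIOError(f"NaN voxels in {spec.name} volume {path}")
    n_ch = arr.shape[4]
    if spec.n_channels is not None and n_ch != spec.n_channels:
        raise VolumeIOError(
            f"{path}: expected {spec.n_channels} channels, found {n_ch}"
        )
    return ImageVolume(
        data=arr,
        affine=np.asarray(img.affine),
        section=spec.name,
        modality_names=[f"modality{i}" for i in range(n_ch)],
    )


def reorient_volume(vol: ImageVolume, target_axcodes: Sequence[str]) -> ImageVolume:
    """Permute/flip spatial axes so the volume is in ``target_axcodes``.

    Purely lossless: no resampling; the affine is updated consistently.
    """
    current = nib.orientations.io_orientation(vol.affine)
    target = nib.orientations.axcodes2ornt(tuple(target_axcodes))
    transform = nib.orientations.ornt_transform(current, target)
    data = nib.orientations.apply_orientation(vol.data, transform)
    new_affine = vol.affine @ nib.orientations.inv_ornt_aff(
        transform, vol.spatial_shape
    )
    return replace(vol, data=data, affine=new_affine)


def reorient_and_concat(
    volumes: Sequence[ImageVolume], target_axcodes: Sequence[str] = ("R", "A", "S")
) -> ImageVolume:
    """Reorient every volume to ``target_axcodes`` and stack channels."""
    if not volumes:
        raise VolumeIOError("no volumes to concatenate")
    oriented = [reorient_volume(v, target_axcodes) for v in volumes]
    shapes = [v.spatial_shape for v in oriented]
    if len(set(shapes)) != 1:
        raise VolumeIOError(f"spatial shapes differ after reorientation: {shapes}")
    data = np.concatenate([v.data for v in oriented], axis=4)
    names = [m for v in oriented for m in v.modality_names]
    return ImageVolume(
        data=data,
        affine=oriented[0].affine,
        section=oriented[0].section,
        modality_names=names,
    )


def write_volume(
    vol: ImageVolume, path: str | Path, reference: ImageVolume | None = None
) -> Path:
    """Write a NIfTI file; the reference (if given) supplies the affine."""
    path = Path(path)
    affine = reference.affine if reference is not None else vol.affine
    if vol.data.shape[3:] == (1, 1):
        data = np.squeeze(vol.data, axis=(3, 4))
    elif vol.data.shape[3] == 1:
        data = np.squeeze(vol.data, axis=3)  # (x,y,z,channels)
    else:
        data = vol.data
    img = nib.Nifti1Image(data, affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write volume to {path}: {exc}") from exc
    return path
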