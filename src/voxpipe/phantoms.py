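"""Synthetic multi-organ phantoms for exercising the whole pipeline.

Each phantom is a 3-D volume containing ``n_organs`` non-overlapping
ellipsoids ("organs") on a zero background: the label map stores the organ
index, the image gives each organ a constant mean intensity plus i.i.d.
Gaussian noise.  Regression pairs add a target volume whose per-organ
intensity is a fixed affine map of the organ *index* (not of the source
intensity), so a regressor has to learn a per-tissue mapping — the same
structure as synthesizing pseudo-CT from MR.  Everything is a pure function
of the spec and its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .volume_io import DatasetIndex, ImageVolume, load_manifest, write_volume


class PhantomError(RuntimeError):
    pass


#: slope/intercept of the organ-index -> regression-target intensity map
REGRESSION_TARGET_INTERCEPT = 0.0
REGRESSION_TARGET_SLOPE = 1.0


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one phantom.

    ``intensity_means`` are the organ mean intensities (background is organ
    0); organs are ellipsoids with radii 10–25% of the smallest axis,
    placed by rejection sampling so they never overlap.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_organs: int = 3
    intensity_means: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_organs < 1 or self.n_organs > 20:
            raise PhantomError(f"n_organs must be in [1, 20], got {self.n_organs}")
        if self.n_organs > 1 and min(self.shape) < 16:
            raise PhantomError("multi-organ phantoms need shape >= 16 per axis")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.intensity_means is None:
            # unit separation between consecutive organ means; background 0
            self.intensity_means = tuple(float(k) for k in range(self.n_organs + 1))
        if len(self.intensity_means) != self.n_organs + 1:
            raise PhantomError(
                f"need {self.n_organs + 1} intensity means (incl. background), "
                f"got {len(self.intensity_means)}"
            )

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.spacing) + [1.0])


def _place_ellipsoids(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping ellipsoids; returns the label map."""
    shape = np.asarray(spec.shape)
    min_axis = shape.min()
    r_lo, r_hi = 0.10 * min_axis, 0.25 * min_axis
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij"), axis=-1
    ).astype(np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for organ in range(1, spec.n_organs + 1):
        for attempt in range(1000):
            radii = rng.uniform(r_lo, r_hi, size=3)
            centre = rng.uniform(radii, shape - 1 - radii)
            # centre separation test against already placed organs
            ok = all(
                np.linalg.norm(centre - c) > np.max(radii) + np.max(r) + 1.0
                for c, r in placed
            )
            if not ok:
                continue
            dist = (((coords - centre) / radii) ** 2).sum(axis=-1)
            inside = dist <= 1.0
            if not inside.any():
                continue
            labels[inside] = organ
            placed.append((centre, radii))
            break
        else:
            raise PhantomError(
                f"could not place organ {organ} without overlap after 1000 "
                f"rejections; try a larger shape"
            )
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume]:
    """One (image, label) phantom pair, deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    labels = _place_ellipsoids(spec, rng)
    means = np.asarray(spec.intensity_means, dtype=np.float64)
    image = means[labels]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img_vol = ImageVolume(image.astype(np.float32), spec.affine, section="image")
    lab_vol = ImageVolume(labels, spec.affine, section="label")
    return img_vol, lab_vol


def regression_target_value(organ_index: int) -> float:
    """The fixed per-tissue map the regression target is built from."""
    return REGRESSION_TARGET_INTERCEPT + REGRESSION_TARGET_SLOPE * organ_index


def generate_regression_pair(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """(source, target, label) sharing one geometry.

    The target's per-organ mean is ``regression_target_value(organ)`` — a
    function of the organ index, not of the source intensity — with
    independent noise of the same standard deviation.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _place_ellipsoids(spec, rng)
    src_means = np.asarray(spec.intensity_means, dtype=np.float64)
    tgt_means = np.array(
        [regression_target_value(k) for k in range(spec.n_organs + 1)]
    )
    source = src_means[labels]
    target = tgt_means[labels]
    if spec.noise_sd > 0:
        source = source + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        target = target + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return (
        ImageVolume(source.astype(np.float32), spec.affine, section="image"),
        ImageVolume(target.astype(np.float32), spec.affine, section="target"),
        ImageVolume(labels, spec.affine, section="label"),
    )


def generate_conditioning_map(shape) -> ImageVolume:
    """3-channel volume; channel k is the normalized coordinate on axis k."""
    shape = tuple(int(s) for s in np.atleast_1d(shape))
    if len(shape) == 1:
        shape = shape * 3
    if len(shape) != 3 or min(shape) <= 0:
        raise PhantomError(f"bad conditioning-map shape {shape}")
    channels = []
    for ax, dim in enumerate(shape):
        ramp = np.arange(dim, dtype=np.float32) / max(dim - 1, 1)
        view = [1, 1, 1]
        view[ax] = dim
        channels.append(np.broadcast_to(ramp.reshape(view), shape))
    data = np.stack(channels, axis=-1)[:, :, :, np.newaxis, :]  # (x,y,z,1,3)
    return ImageVolume(
        data, np.eye(4), section="image",
        modality_names=["coord_x", "coord_y", "coord_z"],
    )


def write_phantom_dataset(
    spec: PhantomSpec,
    n_subjects: int,
    out_dir: str | Path,
    kind: str = "segmentation",
) -> Path:
    """Write ``n_subjects`` phantoms as NIfTI plus a manifest CSV.

    Files follow the substring convention the pattern-based discovery
    expects (``subject###_image.nii.gz`` / ``_label.nii.gz`` and, for
    regression datasets, ``_target.nii.gz``), and the manifest lists the
    same files, so both discovery paths can be exercised on one directory.
    Per-subject seeds are derived from the master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = ["image", "label"] if kind == "segmentation" else ["image", "target", "label"]
    rows = []
    for i in range(int(n_subjects)):
        sid = f"subject{i:03d}"
        sub_spec = replace(spec, seed=spec.seed * 10007 + i)
        if kind == "segmentation":
            img, lab = generate_phantom(sub_spec)
            vols = {"image": img, "label": lab}
        else:
            src, tgt, lab = generate_regression_pair(sub_spec)
            vols = {"image": src, "target": tgt, "label": lab}
        row = {"subject_id": sid}
        for sec in sections:
            fname = f"{sid}_{sec}.nii.gz"
            write_volume(vols[sec], out_dir / fname)
            row[sec] = fname
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["subject_id"] + sections)
        writer.writeheader()
        writer.writerows(rows)
    return manifest
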