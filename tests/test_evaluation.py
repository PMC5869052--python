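"""Segmentation metrics against hand counts and brute-force oracles."""

import numpy as np
import pytest

from voxpipe.evaluation import (
    EvaluationError,
    confusion_counts,
    descriptive_stats,
    evaluate_subjects,
    overlap_metrics,
    region_metrics,
    surface_distances,
    surface_voxels,
    volume_metrics,
)
from voxpipe.volume_io import load_manifest


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_surface(mask):
    """Foreground voxels with a six-connected background neighbour."""
    mask = np.asarray(mask, bool)
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if (n < 0).any() or (n >= mask.shape).any() or not mask[tuple(n)]:
                    out[tuple(idx)] = True
                    break
            if out[tuple(idx)]:
                break
    return out


def brute_distances(seg, ref, spacing=(1.0, 1.0, 1.0)):
    """All-pairs O(n^2) pooled bidirectional surface distances."""
    ps = np.argwhere(brute_surface(seg)) * np.asarray(spacing)
    pr = np.argwhere(brute_surface(ref)) * np.asarray(spacing)
    d = np.sqrt(((ps[:, None, :] - pr[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return {
        "mean_absolute_distance": pooled.mean(),
        "hausdorff": pooled.max(),
        "hausdorff95": np.percentile(pooled, 95),
    }


def brute_overlap(seg, ref):
    s, r = np.asarray(seg, bool), np.asarray(ref, bool)
    tp = (s & r).sum()
    fp = (s & ~r).sum()
    fn = (~s & r).sum()
    tn = (~s & ~r).sum()
    tot = s.size
    def rat(a, b):
        return a / b if b else float("nan")
    return {
        "dice": rat(2 * tp, 2 * tp + fp + fn),
        "jaccard": rat(tp, tp + fp + fn),
        "sensitivity": rat(tp, tp + fn),
        "specificity": rat(tn, tn + fp),
        "accuracy": rat(tp + tn, tot),
    }


def _random_mask(rng, shape=(8, 8, 8), p=0.2):
    return (rng.random(shape) < p).astype(np.int16)


class TestConfusionAndOverlap:
    def test_identical_masks_have_no_errors(self, rng):
        m = _random_mask(rng)
        c = confusion_counts(m, m, 1)
        assert c.fp == 0 and c.fn == 0
        assert all(v == 1.0 for v in overlap_metrics(c).values())

    def test_empty_prediction_counts_all_misses(self):
        ref = np.zeros((4, 4, 4), dtype=int)
        ref[:2, 0, 0] = 1
        c = confusion_counts(np.zeros_like(ref), ref, 1)
        assert c.tp == 0 and c.fn == 2

    def test_hand_counted_toy(self):
        seg = np.zeros((2, 2, 1), dtype=int)
        ref = np.zeros((2, 2, 1), dtype=int)
        seg[0, 0, 0] = 1
        ref[0, 0, 0] = ref[1, 0, 0] = 1
        c = confusion_counts(seg, ref, 1)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 2)
        m = overlap_metrics(c)
        assert m["dice"] == pytest.approx(2 / 3)
        assert m["jaccard"] == pytest.approx(1 / 2)
        assert m["sensitivity"] == pytest.approx(1 / 2)
        assert m["specificity"] == 1.0
        assert m["accuracy"] == pytest.approx(3 / 4)

    def test_both_empty_gives_nan_dice_specificity_one(self):
        z = np.zeros((3, 3, 3), dtype=int)
        m = overlap_metrics(confusion_counts(z, z, 1))
        assert np.isnan(m["dice"]) and m["specificity"] == 1.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(30):
            seg, ref = _random_mask(rng), _random_mask(rng)
            ours = overlap_metrics(confusion_counts(seg, ref, 1))
            oracle = brute_overlap(seg, ref)
            for k in oracle:
                if np.isnan(oracle[k]):
                    assert np.isnan(ours[k])
                else:
                    assert abs(ours[k] - oracle[k]) < 1e-9

    def test_dice_jaccard_identity(self, rng):
        for _ in range(20):
            m = overlap_metrics(confusion_counts(_random_mask(rng), _random_mask(rng), 1))
            if not np.isnan(m["jaccard"]):
                assert m["dice"] == pytest.approx(2 * m["jaccard"] / (1 + m["jaccard"]))

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(EvaluationError, match="shape"):
            confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)), 1)


class TestVolumeMetrics:
    def test_voxel_count_times_spacing(self):
        seg = np.zeros((5, 5, 5), dtype=int)
        seg.ravel()[:10] = 1
        out = volume_metrics(seg, seg, (2.0, 2.0, 2.0))
        assert out["volume_mm3"] == pytest.approx(80.0)
        assert out["relative_volume_difference"] == 0.0

    def test_relative_difference(self):
        seg = np.zeros((4, 4, 4), dtype=int)
        ref = np.zeros((4, 4, 4), dtype=int)
        seg.ravel()[:12] = 1
        ref.ravel()[:10] = 1
        out = volume_metrics(seg, ref, (1, 1, 1))
        assert out["relative_volume_difference"] == pytest.approx(0.2)

    def test_empty_reference_gives_nan(self):
        seg = np.ones((2, 2, 2), dtype=int)
        out = volume_metrics(seg, np.zeros_like(seg), (1, 1, 1))
        assert np.isnan(out["relative_volume_difference"])


class TestSurfaceDistances:
    def test_identical_masks_have_zero_distances(self, rng):
        m = np.zeros((6, 6, 6), dtype=int)
        m[2:5, 2:5, 2:5] = 1
        d = surface_distances(m, m)
        assert d["mean_absolute_distance"] == 0 == d["hausdorff"] == d["hausdorff95"]

    def test_two_single_voxels_three_apart(self):
        a = np.zeros((8, 4, 4), dtype=int)
        b = np.zeros((8, 4, 4), dtype=int)
        a[2, 1, 1] = 1
        b[5, 1, 1] = 1
        d = surface_distances(a, b)
        assert d["mean_absolute_distance"] == pytest.approx(3.0)
        assert d["hausdorff"] == pytest.approx(3.0)
        assert d["hausdorff95"] == pytest.approx(3.0)

    def test_shifted_cube_matches_brute_force(self):
        a = np.zeros((8, 8, 8), dtype=int)
        b = np.zeros((8, 8, 8), dtype=int)
        a[1:5, 1:5, 1:5] = 1
        b[2:6, 1:5, 1:5] = 1
        ours = surface_distances(a, b)
        oracle = brute_distances(a, b)
        for k in oracle:
            assert abs(ours[k] - oracle[k]) < 1e-9

    def test_matches_brute_force_on_random_masks_with_spacing(self, rng):
        for _ in range(20):
            seg = _random_mask(rng, (7, 6, 5), 0.25)
            ref = _random_mask(rng, (7, 6, 5), 0.25)
            if not seg.any() or not ref.any():
                continue
            spacing = rng.uniform(0.5, 3.0, 3)
            ours = surface_distances(seg, ref, spacing)
            oracle = brute_distances(seg, ref, spacing)
            for k in oracle:
                assert abs(ours[k] - oracle[k]) < 1e-9

    def test_symmetry(self, rng):
        seg = _random_mask(rng, (6, 6, 6), 0.3)
        ref = _random_mask(rng, (6, 6, 6), 0.3)
        d1 = surface_distances(seg, ref)
        d2 = surface_distances(ref, seg)
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)

    def test_empty_mask_gives_nan(self):
        m = np.zeros((3, 3, 3), dtype=int)
        m2 = m.copy()
        m2[1, 1, 1] = 1
        assert np.isnan(surface_distances(m, m2)["hausdorff"])

    def test_axis_permutation_invariance(self, rng):
        seg = _random_mask(rng, (6, 5, 4), 0.3)
        ref = _random_mask(rng, (6, 5, 4), 0.3)
        spacing = (1.0, 2.0, 0.5)
        base = surface_distances(seg, ref, spacing)
        perm = (2, 0, 1)
        permuted = surface_distances(
            seg.transpose(perm), ref.transpose(perm),
            tuple(spacing[p] for p in perm),
        )
        for k in base:
            assert base[k] == pytest.approx(permuted[k], abs=1e-12)


class TestRegionMetrics:
    def _two_blobs(self):
        ref = np.zeros((10, 6, 6), dtype=int)
        ref[1:3, 1:3, 1:3] = 1
        ref[6:9, 2:5, 2:5] = 1
        return ref

    def test_perfect_segmentation_detects_everything(self):
        ref = self._two_blobs()
        out = region_metrics(ref, ref)
        assert out["detection_rate"] == 1.0
        assert out["region_specificity"] == 1.0
        assert out["region_accuracy"] == 1.0

    def test_missing_one_of_two_components(self):
        ref = self._two_blobs()
        seg = np.zeros_like(ref)
        seg[1:3, 1:3, 1:3] = 1  # covers only the first blob
        out = region_metrics(seg, ref)
        assert out["detection_rate"] == 0.5

    def test_spurious_component_lowers_region_specificity(self):
        ref = self._two_blobs()
        seg = ref.copy()
        seg[4, 0, 0] = 1  # extra isolated component
        out = region_metrics(seg, ref)
        assert out["region_specificity"] == pytest.approx(1 - 1 / 3)


class TestDescriptiveStats:
    def test_single_voxel_surface_and_volume(self):
        m = np.zeros((3, 3, 3), dtype=int)
        m[1, 1, 1] = 1
        out = descriptive_stats(m, np.ones((3, 3, 3)))
        assert out["volume_mm3"] == 1.0
        assert out["surface_mm2"] == 6.0
        assert out["surface_volume_ratio"] == 6.0

    def test_symmetric_intensities_have_zero_skewness(self):
        m = np.ones((2, 2, 2), dtype=int)
        img = np.array([1, 2, 2, 3, 1, 2, 2, 3], dtype=float).reshape(2, 2, 2)
        out = descriptive_stats(m, img)
        assert abs(out["intensity_skewness"]) < 1e-9

    def test_constant_intensity_collapses_quartiles(self):
        m = np.ones((2, 2, 2), dtype=int)
        out = descriptive_stats(m, np.full((2, 2, 2), 4.5))
        assert out["intensity_q25"] == out["intensity_median"] == \
            out["intensity_q75"] == out["intensity_mean"] == 4.5

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EvaluationError, match="empty"):
            descriptive_stats(np.zeros((2, 2, 2), dtype=int), np.ones((2, 2, 2)))


class TestEvaluateSubjects:
    def test_identical_segmentations_score_dice_one(self, tmp_path, seg_dataset):
        import shutil
        data_dir, manifest = seg_dataset
        index = load_manifest(manifest)
        seg_dir = tmp_path / "segs"
        seg_dir.mkdir()
        for sid in index.subject_ids:
            shutil.copy(index.subjects[sid]["label"],
                        seg_dir / f"{sid}_niftynet_out.nii.gz")
        report = evaluate_subjects(index, seg_dir, metrics=("dice",),
                                   csv_path=tmp_path / "report.csv")
        assert (report["value"] == 1.0).all()
        assert (tmp_path / "report.csv").exists()
        # rows = subjects x labels x metrics + median aggregate rows
        n_labels = report[report.subject_id != "median"]["label"].nunique()
        assert len(report[report.subject_id != "median"]) == len(index) * n_labels

    def test_metric_selection_restricts_rows(self, tmp_path, seg_dataset):
        import shutil
        data_dir, manifest = seg_dataset
        index = load_manifest(manifest)
        seg_dir = tmp_path / "segs"
        seg_dir.mkdir()
        for sid in index.subject_ids:
            shutil.copy(index.subjects[sid]["label"],
                        seg_dir / f"{sid}_niftynet_out.nii.gz")
        report = evaluate_subjects(index, seg_dir, metrics=("dice", "jaccard"))
        assert set(report["metric"]) == {"dice", "jaccard"}

    def test_missing_segmentation_error_names_subject(self, tmp_path, seg_dataset):
        _, manifest = seg_dataset
        index = load_manifest(manifest)
        with pytest.raises(EvaluationError, match="subject000"):
            evaluate_subjects(index, tmp_path, metrics=("dice",))


def test_surface_voxels_match_brute_force(rng):
    for _ in range(10):
        m = _random_mask(rng, (6, 6, 6), 0.4)
        np.testing.assert_array_equal(surface_voxels(m.astype(bool)), brute_surface(m))
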