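"""Intensity normalization, landmark standardization and augmentation."""

import numpy as np
import pytest

from voxpipe.phantoms import PhantomSpec, write_phantom_dataset
from voxpipe.preprocessing import (
    AugmentationParams,
    LandmarkModel,
    PreprocessingError,
    apply_transform,
    histogram_standardize,
    meanvar_normalize,
    sample_affine,
    train_landmarks,
    DEFAULT_PERCENTILES,
)
from voxpipe.volume_io import DatasetIndex, load_manifest, reorient_and_concat

from conftest import make_volume


class TestMeanVar:
    def test_output_has_zero_mean_unit_sd(self, rng):
        vol = make_volume(rng.random((6, 6, 6)) * 50 + 7)
        out = meanvar_normalize(vol)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1.0) < 1e-6

    def test_idempotence(self, rng):
        vol = make_volume(rng.random((5, 5, 5)))
        once = meanvar_normalize(vol)
        twice = meanvar_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_constant_channel_is_an_error(self):
        with pytest.raises(PreprocessingError, match="zero variance.*0|channel 0"):
            meanvar_normalize(make_volume(np.full((4, 4, 4), 3.0)))

    def test_masked_stats_apply_same_map_everywhere(self, rng):
        arr = rng.random((6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[:3] = True
        out = meanvar_normalize(make_volume(arr), mask)
        inside = out.data[:3]
        assert abs(inside.mean()) < 1e-6 and abs(inside.std() - 1) < 1e-6
        # affine map: correlation with input preserved exactly outside too
        np.testing.assert_allclose(
            np.corrcoef(out.data.ravel(), arr.ravel())[0, 1], 1.0, atol=1e-12
        )


def _brute_force_standardize(values, percentiles, target):
    """Oracle: piecewise-linear landmark mapping with end extrapolation."""
    knots = np.percentile(values, percentiles)
    out = np.empty_like(values, dtype=float)
    for i, v in enumerate(values.ravel()):
        if v <= knots[0]:
            j = 0
        elif v >= knots[-1]:
            j = len(knots) - 2
        else:
            j = np.searchsorted(knots, v, side="right") - 1
            j = min(j, len(knots) - 2)
        k0, k1 = knots[j], knots[j + 1]
        frac = 0.0 if k1 == k0 else (v - k0) / (k1 - k0)
        out.ravel()[i] = target[j] + frac * (target[j + 1] - target[j])
    return out.reshape(values.shape)


class TestHistogramStandardization:
    def _single_image_model(self, tmp_path, arr):
        vol = make_volume(arr)
        from voxpipe.volume_io import write_volume
        p = tmp_path / "img_image.nii.gz"
        write_volume(vol, p)
        idx = DatasetIndex(subjects={"img": {"image": p}})
        return train_landmarks(idx)

    def test_single_image_training_maps_own_percentiles_to_scale(self, tmp_path, rng):
        # 101 distinct values put every probed integer rank exactly on a
        # data value, so the knot mapping is observable without
        # order-statistic interpolation error
        arr = rng.permutation(np.linspace(3.0, 97.0, 101)).reshape(101, 1, 1)
        model = self._single_image_model(tmp_path, arr)
        out = histogram_standardize(make_volume(arr), model)
        probed = np.percentile(out.data, model.percentiles)
        np.testing.assert_allclose(probed, model.standard_scale, atol=1e-6)

    def test_two_identical_images_give_same_landmarks_as_one(self, tmp_path, rng):
        arr = rng.random((6, 6, 6)) * 10
        from voxpipe.volume_io import write_volume
        for name in ("a_image.nii.gz", "b_image.nii.gz"):
            write_volume(make_volume(arr), tmp_path / name)
        one = DatasetIndex(subjects={"a": {"image": tmp_path / "a_image.nii.gz"}})
        two = DatasetIndex(subjects={
            "a": {"image": tmp_path / "a_image.nii.gz"},
            "b": {"image": tmp_path / "b_image.nii.gz"},
        })
        np.testing.assert_allclose(
            train_landmarks(one).per_modality_landmarks["modality0"],
            train_landmarks(two).per_modality_landmarks["modality0"],
            atol=1e-9,
        )

    def test_shifted_training_image_gives_identical_landmarks(self, tmp_path, rng):
        arr = rng.random((6, 6, 6)) * 10
        from voxpipe.volume_io import write_volume
        write_volume(make_volume(arr), tmp_path / "a_image.nii.gz")
        write_volume(make_volume(arr + 100.0), tmp_path / "b_image.nii.gz")
        la = train_landmarks(DatasetIndex(subjects={"a": {"image": tmp_path / "a_image.nii.gz"}}))
        lb = train_landmarks(DatasetIndex(subjects={"b": {"image": tmp_path / "b_image.nii.gz"}}))
        np.testing.assert_allclose(
            la.per_modality_landmarks["modality0"],
            lb.per_modality_landmarks["modality0"], atol=1e-9,
        )

    def test_matches_piecewise_linear_oracle(self, tmp_path, rng):
        arr = rng.random(100).reshape(5, 5, 4) * 40
        model = self._single_image_model(tmp_path, arr)
        out = histogram_standardize(make_volume(arr), model)
        oracle = _brute_force_standardize(
            arr, model.percentiles, model.standard_scale
        )
        np.testing.assert_allclose(np.squeeze(out.data), oracle, atol=1e-8)

    def test_affine_intensity_invariance_and_monotonicity(self, tmp_path, rng):
        base = rng.random((5, 5, 5)) * 20
        model = self._single_image_model(tmp_path, base)
        for _ in range(10):
            arr = rng.random((5, 5, 5)) * rng.uniform(1, 50) + rng.uniform(-30, 30)
            out1 = histogram_standardize(make_volume(arr), model)
            out2 = histogram_standardize(make_volume(arr * 3.0 + 17.0), model)
            np.testing.assert_allclose(out1.data, out2.data, atol=1e-6)
            a, b = arr.ravel(), np.squeeze(out1.data).ravel()
            order = np.argsort(a)
            assert np.all(np.diff(b[order]) >= -1e-9)

    def test_untrained_modality_is_an_error(self, tmp_path, rng):
        model = self._single_image_model(tmp_path, rng.random((5, 5, 5)))
        vol = make_volume(rng.random((5, 5, 5, 1, 1)))
        vol.modality_names[0] = "T2"
        with pytest.raises(PreprocessingError, match="T2"):
            histogram_standardize(vol, model)

    def test_landmark_file_round_trip(self, tmp_path, rng):
        model = self._single_image_model(tmp_path, rng.random((6, 6, 6)) * 9)
        path = model.save(tmp_path / "landmarks.txt")
        back = LandmarkModel.load(path)
        np.testing.assert_allclose(back.percentiles, model.percentiles)
        np.testing.assert_allclose(
            back.per_modality_landmarks["modality0"],
            model.per_modality_landmarks["modality0"], atol=1e-9,
        )


class TestAffineAugmentation:
    def test_degenerate_ranges_give_identity(self, rng):
        params = AugmentationParams(rotation_range_deg=(0, 0), scaling_range_pct=(100, 100))
        np.testing.assert_allclose(sample_affine(params, rng), np.eye(4), atol=1e-12)

    def test_same_seed_gives_same_matrix(self):
        params = AugmentationParams(flip_axes=(0, 2), rotation_range_deg=(-30, 30),
                                    scaling_range_pct=(80, 120))
        m1 = sample_affine(params, np.random.default_rng(9))
        m2 = sample_affine(params, np.random.default_rng(9))
        np.testing.assert_array_equal(m1, m2)

    def test_pure_scaling_determinant(self, rng):
        params = AugmentationParams(scaling_range_pct=(200, 200))
        m = sample_affine(params, rng)
        assert abs(np.linalg.det(m[:3, :3]) - 8.0) < 1e-9

    def test_identity_transform_is_a_noop_for_all_sections(self, rng):
        img = make_volume(rng.random((6, 6, 6)))
        lab = make_volume(rng.integers(0, 3, (6, 6, 6)).astype(np.int16), section="label")
        out_img, out_lab = apply_transform([img, lab], np.eye(4))
        np.testing.assert_allclose(out_img.data, img.data)
        np.testing.assert_array_equal(out_lab.data, lab.data)

    def test_flip_applied_twice_restores_volume(self, rng):
        img = make_volume(rng.random((6, 6, 6)))
        flip = np.diag([-1.0, 1.0, 1.0, 1.0])
        once = apply_transform([img], flip)[0]
        twice = apply_transform([once], flip)[0]
        np.testing.assert_allclose(twice.data, img.data, atol=1e-9)

    def test_label_values_closed_under_rotation(self, rng):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[3:7, 3:7, 3:7] = 2
        lab[4:6, 4:6, 4:6] = 5
        vol = make_volume(lab, section="label")
        rot = sample_affine(
            AugmentationParams(rotation_range_deg=(7, 7)), np.random.default_rng(0)
        )
        out = apply_transform([vol], rot)[0]
        assert set(np.unique(out.data)) <= {0, 2, 5}

    def test_transform_commutes_with_channel_concat(self, rng):
        a = make_volume(rng.random((5, 5, 5)))
        b = make_volume(rng.random((5, 5, 5)))
        t = sample_affine(
            AugmentationParams(rotation_range_deg=(-15, 15), scaling_range_pct=(90, 110)),
            np.random.default_rng(3),
        )
        separate = apply_transform([a, b], t)
        joint = apply_transform([reorient_and_concat([a, b])], t)[0]
        np.testing.assert_allclose(
            joint.data[:, :, :, 0, 0], np.squeeze(separate[0].data), atol=1e-9)
        np.testing.assert_allclose(
            joint.data[:, :, :, 0, 1], np.squeeze(separate[1].data), atol=1e-9)

    def test_non_invertible_transform_is_an_error(self, rng):
        bad = np.zeros((4, 4))
        with pytest.raises(PreprocessingError, match="invertible"):
            apply_transform([make_volume(rng.random((4, 4, 4)))], bad)
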