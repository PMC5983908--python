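"""Registration chain: flip, landmark alignment, resampling, ECC,
standardization."""

import numpy as np
import pytest

from rnflpca.config import CohortConfig
from rnflpca.maps import ThicknessMap
from rnflpca.registration import (apply_standardization, canonical_landmarks,
                                  ecc_register, fit_standardization,
                                  flip_to_od, landmark_similarity, resample)
from rnflpca.simulate import generate_template_map
from rnflpca.transforms import SimilarityTransform


@pytest.fixture(scope="module")
def od_template():
    return generate_template_map(CohortConfig())


def _os_map(od_template):
    m = od_template.copy_with(values=od_template.values[:, ::-1].copy(),
                              laterality="OS", od_oriented=False)
    w = od_template.shape[1]
    return m.copy_with(fovea_xy=((w - 1) - od_template.fovea_xy[0],
                                 od_template.fovea_xy[1]),
                       onh_xy=((w - 1) - od_template.onh_xy[0],
                               od_template.onh_xy[1]))


class TestFlip:
    def test_od_map_is_unchanged(self, od_template):
        out = flip_to_od(od_template)
        assert np.array_equal(out.values, od_template.values)
        assert out.od_oriented

    def test_flip_is_involutive_on_values(self, od_template):
        os_map = _os_map(od_template)
        once = flip_to_od(os_map)
        assert np.array_equal(once.values, od_template.values)
        # mirroring the flipped map again restores the original
        assert np.array_equal(once.values[:, ::-1], os_map.values)

    def test_fovea_x_mirrored(self, od_template):
        os_map = _os_map(od_template)
        out = flip_to_od(os_map)
        w = od_template.shape[1]
        assert out.fovea_xy[0] == pytest.approx((w - 1) - os_map.fovea_xy[0])


class TestLandmarkSimilarity:
    def test_identity_when_pairs_coincide(self):
        t = landmark_similarity((10, 20), (40, 25), (10, 20), (40, 25))
        assert t.is_close(SimilarityTransform.identity(), atol=1e-12)

    def test_pure_translation(self):
        t = landmark_similarity((10, 20), (40, 25), (15, 17), (45, 22))
        assert t.scale == pytest.approx(1.0)
        assert t.theta == pytest.approx(0.0)
        assert (t.tx, t.ty) == (pytest.approx(5.0), pytest.approx(-3.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_recovers_inverse(self, seed):
        rng = np.random.default_rng(seed)
        T = SimilarityTransform(scale=rng.uniform(0.7, 1.4),
                                theta=rng.uniform(-1.0, 1.0),
                                tx=rng.uniform(-10, 10),
                                ty=rng.uniform(-10, 10))
        ref_f, ref_o = np.array([99.0, 60.0]), np.array([48.0, 56.0])
        src_f, src_o = T.apply(ref_f), T.apply(ref_o)
        rec = landmark_similarity(src_f, src_o, ref_f, ref_o)
        assert rec.is_close(T.inverse(), atol=1e-9)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            landmark_similarity((10, 10), (10, 10), (0, 0), (5, 5))


class TestResample:
    def test_identity_preserves_values(self, od_template):
        out = resample(od_template, SimilarityTransform.identity())
        assert np.allclose(out.values, od_template.values)

    def test_integer_translation_of_constant_map(self):
        cfg = CohortConfig()
        const = ThicknessMap(values=np.full((120, 160), 70.0),
                             laterality="OD", fovea_xy=(99, 60),
                             onh_xy=(48, 56), um_per_px=cfg.um_per_px)
        out = resample(const, SimilarityTransform(1.0, 0.0, 7.0, -4.0))
        ok = np.isfinite(out.values)
        assert np.allclose(out.values[ok], 70.0)

    def test_subpixel_round_trip_on_smooth_map(self, od_template):
        fwd = SimilarityTransform(1.0, 0.0, 3.5, 0.0)
        there = resample(od_template, fwd)
        back = resample(there, fwd.inverse())
        ok = np.isfinite(back.values)
        diff = np.abs(back.values[ok] - od_template.values[ok])
        assert diff.max() < 1.0

    def test_landmarks_follow_transform(self, od_template):
        t = SimilarityTransform(1.1, 0.2, 5.0, -3.0)
        out = resample(od_template, t)
        assert np.allclose(out.fovea_xy,
                           t.apply(np.asarray(od_template.fovea_xy)))


class TestECC:
    def test_self_registration_is_identity(self, od_template):
        res = ecc_register(od_template.values, od_template.values)
        assert res.converged
        assert res.ecc > 0.9999
        assert res.transform.is_close(SimilarityTransform.identity(),
                                      atol=1e-2)

    def test_translation_recovery(self, od_template):
        T = SimilarityTransform(1.0, 0.0, 4.0, 0.0)
        moving = resample(od_template, T.inverse())
        res = ecc_register(moving.values, od_template.values,
                           motion="euclidean")
        assert res.converged
        assert abs(res.transform.tx - 4.0) < 0.25
        assert abs(res.transform.ty) < 0.25

    def test_rotation_recovery(self, od_template):
        h, w = od_template.shape
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        theta = np.deg2rad(3.0)
        rot = SimilarityTransform(1.0, theta, 0.0, 0.0)
        shift = rot.apply(c) - c
        T = SimilarityTransform(1.0, theta, -shift[0], -shift[1])
        moving = resample(od_template, T)
        res = ecc_register(moving.values, od_template.values,
                           motion="euclidean")
        want = T.inverse()
        assert res.converged
        assert abs(np.rad2deg(res.transform.theta - want.theta)) < 0.2

    def test_similarity_recovery_including_scale(self, od_template):
        T = SimilarityTransform(1.04, np.deg2rad(-2.0), 3.0, -2.0)
        moving = resample(od_template, T)
        res = ecc_register(moving.values, od_template.values,
                           motion="similarity")
        want = T.inverse()
        assert res.converged
        assert abs(res.transform.scale - want.scale) < 0.01
        assert abs(np.rad2deg(res.transform.theta - want.theta)) < 0.2

    def test_shape_mismatch_rejected(self, od_template):
        with pytest.raises(ValueError, match="shape"):
            ecc_register(od_template.values[:-1], od_template.values)


class TestStandardization:
    def test_training_stack_standardizes_to_zero_mean_unit_var(self, rng):
        stack = rng.normal(80.0, 12.0, size=(30, 20, 25))
        model = fit_standardization(stack)
        z = apply_standardization(stack, model)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.var(axis=0) - 1.0).max() < 1e-6

    def test_constant_pixel_maps_to_zero(self, rng):
        stack = rng.normal(80.0, 12.0, size=(10, 5, 5))
        stack[:, 2, 2] = 55.0
        model = fit_standardization(stack)
        z = apply_standardization(stack, model)
        assert np.allclose(z[:, 2, 2], 0.0)

    def test_held_out_map_equal_to_mean_is_all_zero(self, rng):
        stack = rng.normal(80.0, 12.0, size=(10, 5, 5))
        model = fit_standardization(stack)
        z = apply_standardization(model.mean, model)
        assert np.allclose(z, 0.0)

    def test_nan_pixels_excluded_from_fit_and_imputed_on_apply(self, rng):
        stack = rng.normal(80.0, 12.0, size=(20, 6, 6))
        stack[:10, 0, 0] = np.nan
        model = fit_standardization(stack)
        assert model.counts[0, 0] == 10
        z = apply_standardization(stack, model)
        assert np.isfinite(z).all()

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            fit_standardization(np.zeros((1, 4, 4)))


def test_canonical_frame_is_od_oriented():
    fovea, onh = canonical_landmarks((120, 160))
    assert onh[0] < fovea[0]  # nerve head nasal (left) of fovea
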