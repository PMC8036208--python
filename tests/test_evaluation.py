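"""Voxel metrics, Bland-Altman, R^2, lesion segmentation, VOIs, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from voxdose.evaluation import (bland_altman, joint_histogram_r2,
                                line_profile, segment_lesion_suv,
                                voi_mean_dose, voxel_metrics)
from voxdose.volumes import Volume


class TestVoxelMetrics:
    def test_identical_volumes_zero_errors(self):
        a = np.random.default_rng(0).random((5, 5, 5))
        m = voxel_metrics(a, a)
        assert m.mae == m.mrae_pct == m.rmse == 0

    def test_hand_worked_two_voxel_example(self):
        pred = np.array([2.0, 2.0]).reshape(1, 1, 2)
        ref = np.array([1.0, 2.0]).reshape(1, 1, 2)
        m = voxel_metrics(pred, ref)
        assert m.mae == pytest.approx(0.5)
        # mean of |2-1|/1 = 1 and |2-2|/2 = 0 -> 50%
        assert m.mrae_pct == pytest.approx(50.0)
        assert m.rmse == pytest.approx(np.sqrt(0.5), rel=1e-6)

    def test_constant_shift_bounded_by_triangle_inequality(self):
        rng = np.random.default_rng(1)
        pred = rng.random((4, 4, 4))
        ref = rng.random((4, 4, 4)) + 0.5
        base = voxel_metrics(pred, ref).mae
        shifted = voxel_metrics(pred + 0.3, ref).mae
        assert shifted <= base + 0.3 + 1e-12

    def test_empty_mask_rejected(self):
        a = np.ones((3, 3, 3))
        with pytest.raises(ValueError):
            voxel_metrics(a, a, np.zeros((3, 3, 3), dtype=bool))

    @given(arrays(np.float64, (64,),
                  elements=st.floats(0.1, 100.0)),
           arrays(np.float64, (64,),
                  elements=st.floats(0.1, 100.0)))
    @settings(max_examples=30, deadline=None)
    def test_rmse_dominates_mae_and_permutation_invariance(self, p, r):
        p3 = p.reshape(4, 4, 4)
        r3 = r.reshape(4, 4, 4)
        m = voxel_metrics(p3, r3)
        assert m.rmse >= m.mae - 1e-12
        perm = np.random.default_rng(0).permutation(64)
        m2 = voxel_metrics(p[perm].reshape(4, 4, 4),
                           r[perm].reshape(4, 4, 4))
        assert m2.mae == pytest.approx(m.mae)
        assert m2.rmse == pytest.approx(m.rmse)
        assert m2.mrae_pct == pytest.approx(m.mrae_pct)


class TestBlandAltman:
    def test_identical_maps(self):
        a = np.random.default_rng(2).random((4, 4, 4)) + 1
        res = bland_altman(a, a)
        assert res.bias_pct == 0
        assert res.loa_lower_pct == res.loa_upper_pct == 0

    def test_constant_relative_offset(self):
        ref = np.random.default_rng(3).random((4, 4, 4)) + 1
        res = bland_altman(1.1 * ref, ref)
        assert res.bias_pct == pytest.approx(10.0)
        assert res.loa_upper_pct - res.loa_lower_pct == pytest.approx(
            0.0, abs=1e-9)

    def test_gaussian_differences_recover_normal_limits(self):
        # differences ~ N(2, 3): limits should approach 2 -/+ 1.96*3
        rng = np.random.default_rng(42)
        n = 100_000
        ref = np.full(n, 100.0)
        pred = ref * (1 + rng.normal(2.0, 3.0, n) / 100.0)
        res = bland_altman(pred.reshape(50, 50, 40),
                           ref.reshape(50, 50, 40))
        assert res.bias_pct == pytest.approx(2.0, abs=0.05)
        assert res.loa_lower_pct == pytest.approx(2 - 1.96 * 3, abs=0.1)
        assert res.loa_upper_pct == pytest.approx(2 + 1.96 * 3, abs=0.1)

    def test_bias_equals_mean_signed_difference(self):
        rng = np.random.default_rng(5)
        ref = rng.random((6, 6, 6)) + 1
        pred = ref * (1 + rng.normal(0, 0.05, ref.shape))
        res = bland_altman(pred, ref)
        signed = (pred - ref) / ref * 100
        assert res.bias_pct == pytest.approx(signed.mean(), rel=1e-9)

    def test_fewer_than_two_voxels_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones((1, 1, 1)), np.ones((1, 1, 1)))


class TestJointHistogramR2:
    def test_identity_and_affine_give_unity(self):
        ref = np.random.default_rng(6).random((5, 5, 5)) + 0.5
        assert joint_histogram_r2(ref, ref) == pytest.approx(1.0)
        assert joint_histogram_r2(3 * ref - 0.2, ref) == pytest.approx(1.0)

    def test_additive_noise_matches_closed_form(self):
        rng = np.random.default_rng(7)
        n = 80_000
        ref = rng.normal(10.0, 2.0, n)
        noise = rng.normal(0.0, 1.0, n)
        got = joint_histogram_r2((ref + noise).reshape(40, 40, 50),
                                 ref.reshape(40, 40, 50))
        want = 4.0 / (4.0 + 1.0)  # var(ref) / (var(ref) + var(noise))
        assert got == pytest.approx(want, abs=0.01)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            joint_histogram_r2(np.ones((3, 3, 3)), np.ones((3, 3, 3)))


class TestLesionSegmentation:
    def test_uniform_sphere_segmented_exactly(self):
        shape = (32, 32, 32)
        idx = np.indices(shape)
        r = np.sqrt(sum((idx[a] - 16) ** 2 for a in range(3)))
        sphere = r <= 6
        pet = np.where(sphere, 100.0, 0.0)
        mask = segment_lesion_suv(pet)
        np.testing.assert_array_equal(mask, sphere)

    def test_fraction_one_keeps_only_max_voxels(self):
        pet = np.zeros((8, 8, 8))
        pet[4, 4, 4] = 10
        pet[2, 2, 2] = 5
        mask = segment_lesion_suv(pet, fraction=1.0)
        assert mask.sum() == 1 and mask[4, 4, 4]

    def test_gaussian_blob_isocontour_radius(self):
        # 42% isocontour of exp(-r^2 / (2 sigma^2)): r* = sigma*sqrt(-2 ln .42)
        shape = (33, 33, 33)
        sigma = 2.0
        idx = np.indices(shape)
        r2 = sum((idx[a] - 16.0) ** 2 for a in range(3))
        pet = np.exp(-r2 / (2 * sigma**2))
        mask = segment_lesion_suv(pet, fraction=0.42)
        r_star = sigma * np.sqrt(-2 * np.log(0.42))
        got = (3 * mask.sum() / (4 * np.pi)) ** (1 / 3)
        assert got == pytest.approx(r_star, abs=1.0)

    def test_zero_region_rejected(self):
        with pytest.raises(ValueError):
            segment_lesion_suv(np.zeros((4, 4, 4)))

    def test_disconnected_component_excluded(self):
        pet = np.zeros((12, 12, 12))
        pet[2:4, 2:4, 2:4] = 80.0
        pet[8:10, 8:10, 8:10] = 100.0
        mask = segment_lesion_suv(pet, fraction=0.42)
        assert mask[9, 9, 9] and not mask[3, 3, 3]


class TestVoiAndProfiles:
    def test_constant_voi(self):
        dose = np.full((4, 4, 4), 2.5)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mean, sd = voi_mean_dose(dose, mask)
        assert mean == 2.5 and sd == 0

    def test_disjoint_vois_combine_by_voxel_count(self):
        dose = np.zeros((6, 6, 6))
        a = np.zeros_like(dose, dtype=bool)
        b = np.zeros_like(dose, dtype=bool)
        a[0, 0, :3] = True
        b[5, 5, :2] = True
        dose[a] = 1.0
        dose[b] = 4.0
        both, _ = voi_mean_dose(dose, a | b)
        wa, _ = voi_mean_dose(dose, a)
        wb, _ = voi_mean_dose(dose, b)
        assert both == pytest.approx((3 * wa + 2 * wb) / 5)

    def test_hand_built_three_voxel_voi(self):
        dose = np.zeros((3, 3, 3))
        mask = np.zeros_like(dose, dtype=bool)
        for i, v in enumerate([1.0, 2.0, 6.0]):
            dose[i, 0, 0] = v
            mask[i, 0, 0] = True
        mean, sd = voi_mean_dose(dose, mask)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.std([1, 2, 6], ddof=1))

    def test_profile_through_delta_peaks_at_source(self):
        vol = Volume(np.zeros((9, 9, 9)), 3.0)
        vol.data[4, 4, 4] = 7.0
        coords, vals = line_profile(vol, axis=0, fixed_indices=(4, 4))
        assert vals.argmax() == 4
        assert coords.size == 9
        assert coords[1] - coords[0] == pytest.approx(3.0)

    def test_profile_of_constant_volume_is_constant(self):
        _, vals = line_profile(np.full((5, 6, 7), 3.3), axis=2,
                               fixed_indices=(1, 2), spacing_mm=3.0)
        assert vals.shape == (7,)
        assert np.allclose(vals, 3.3)

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(IndexError):
            line_profile(np.zeros((4, 4, 4)), 0, (5, 0), spacing_mm=3.0)
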