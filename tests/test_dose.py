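"""Dose engines: cumulated activity, convolution, masked superposition, Gy."""

import numpy as np
import pytest

from voxdose.constants import SOURCE_INDEX
from voxdose.dose import (convolve_kernel, cumulate_activity, dose_msv,
                          dose_specific, dose_ssv, tally_to_gray)
from voxdose.kernels import SSVProvider, homogeneous_patch
from voxdose.materials import default_material_table
from voxdose.phantoms import SOFT_TISSUE, default_frame_times
from voxdose.volumes import (TimeActivitySeries, Volume, VoxelKernel,
                             f18_decay_constant)


def _series(frames, times=None, spacing=3.0):
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float) + 1.0
    return TimeActivitySeries(times_min=times, frames=frames,
                              spacing_mm=spacing)


class TestCumulateActivity:
    def test_all_zero_frames_give_zero_map(self):
        cum = cumulate_activity(_series(np.zeros((3, 4, 4, 4))))
        assert np.all(cum.data == 0)

    def test_single_frame_pure_decay_tail(self):
        lam = f18_decay_constant()
        a = np.full((1, 2, 2, 2), 100.0)
        cum = cumulate_activity(_series(a, times=np.array([0.0 + 1e-9])))
        vol_ml = 0.3**3
        expected = 100.0 / lam * 60.0 * vol_ml
        np.testing.assert_allclose(cum.data, expected, rtol=1e-9)

    def test_exponential_frames_recover_analytic_integral(self):
        # frames sampled from A(t) = A0 exp(-lambda t) at the 13 default
        # mid-times: quadrature + tail must recover A0/lambda closely
        lam = f18_decay_constant()
        t = default_frame_times()
        a0 = 5000.0
        frames = (a0 * np.exp(-lam * t))[:, None, None, None] * \
            np.ones((1, 1, 1))
        cum = cumulate_activity(_series(frames, times=t))
        analytic = a0 / lam * 60.0 * 0.3**3
        # the [0, t0] head is not covered by the frames; bound accordingly
        head = a0 * t[0]
        assert cum.data[0, 0, 0] == pytest.approx(analytic, rel=0.02)

    def test_printed_sum_flag_doubles_frame_integral(self):
        t = np.array([1.0, 2.0, 3.0])
        frames = np.ones((3, 1, 1, 1)) * 100.0
        lam = f18_decay_constant()
        std = cumulate_activity(_series(frames, times=t))
        lit = cumulate_activity(_series(frames, times=t), printed_sum=True)
        vol = 60.0 * 0.3**3
        frame_part = 100.0 * 2.0 * vol     # trapezoid over [1, 3]
        tail = 100.0 / lam * vol
        assert std.data[0, 0, 0] == pytest.approx(frame_part + tail)
        assert lit.data[0, 0, 0] == pytest.approx(2 * frame_part + tail)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            _series(np.zeros((2, 2, 2, 2)), times=np.array([2.0, 1.0]))


class TestTallyToGray:
    def test_unit_conversion_arithmetic(self):
        dens = Volume(np.ones((1, 1, 1)), 3.0)
        gy = tally_to_gray(np.ones((1, 1, 1)), 1.0, dens)
        assert gy[0, 0, 0] == pytest.approx(0.9673 * 1.602176634e-10,
                                            rel=1e-12)

    def test_zero_tally_zero_dose(self):
        dens = Volume(np.ones((2, 2, 2)), 3.0)
        assert np.all(tally_to_gray(np.zeros((2, 2, 2)), 5.0, dens) == 0)

    def test_half_density_doubles_dose(self):
        tally = np.ones((2, 2, 2))
        d1 = tally_to_gray(tally, 1.0, Volume(np.full((2, 2, 2), 1.0), 3.0))
        d2 = tally_to_gray(tally, 1.0, Volume(np.full((2, 2, 2), 0.5), 3.0))
        np.testing.assert_allclose(d2, 2 * d1)

    def test_zero_density_with_tally_rejected(self):
        dens = Volume(np.zeros((1, 1, 1)), 3.0)
        with pytest.raises(ValueError):
            tally_to_gray(np.ones((1, 1, 1)), 1.0, dens)


def _toy_kernel(n=5):
    rng = np.random.default_rng(3)
    dep = rng.random((n, n, n))
    return VoxelKernel(dep, spacing_mm=3.0, source_index=(n // 2,) * 3)


class TestConvolution:
    def test_fft_equals_brute_force_on_16_cube(self):
        rng = np.random.default_rng(1)
        act = np.zeros((16, 16, 16))
        act[tuple(rng.integers(0, 16, (10, 3)).T)] = rng.random(10) * 5
        kern = _toy_kernel(5)
        fft = convolve_kernel(act, kern.deposition, kern.source_index, "fft")
        direct = convolve_kernel(act, kern.deposition, kern.source_index,
                                 "direct")
        assert np.max(np.abs(fft - direct)) <= 1e-10 * direct.max()

    def test_delta_activity_reproduces_kernel(self, soft_kernel):
        mt = default_material_table()
        patch = homogeneous_patch(SOFT_TISSUE)
        cum = np.zeros(patch.shape)
        cum[SOURCE_INDEX] = 1.0
        dose = dose_ssv(Volume(cum, 3.0), soft_kernel, patch)
        want = tally_to_gray(soft_kernel.deposition, 1.0, patch)
        np.testing.assert_allclose(dose.data, want, rtol=1e-9, atol=1e-30)

    def test_linearity_in_cumulated_activity(self, soft_kernel):
        patch = homogeneous_patch(SOFT_TISSUE)
        rng = np.random.default_rng(2)
        cum = Volume(rng.random(patch.shape) * 100, 3.0)
        d1 = dose_ssv(cum, soft_kernel, patch)
        d2 = dose_ssv(Volume(cum.data * 2, 3.0), soft_kernel, patch)
        np.testing.assert_allclose(d2.data, 2 * d1.data, rtol=1e-9)

    def test_spacing_mismatch_rejected(self, soft_kernel):
        patch = homogeneous_patch(SOFT_TISSUE)
        with pytest.raises(ValueError):
            dose_ssv(Volume(np.ones(patch.shape), 2.0), soft_kernel,
                     Volume(np.ones(patch.shape), 2.0))


class TestMsv:
    def test_reduces_to_ssv_on_all_soft_phantom(self, msv_library,
                                                soft_kernel):
        patch = homogeneous_patch(SOFT_TISSUE)
        mats = Volume(np.full(patch.shape, SOFT_TISSUE), 3.0)
        rng = np.random.default_rng(4)
        cum = Volume(rng.random(patch.shape), 3.0)
        via_msv = dose_msv(cum, msv_library, mats, patch)
        via_ssv = dose_ssv(cum, soft_kernel, patch)
        np.testing.assert_array_equal(via_msv.data, via_ssv.data)

    def test_empty_library_rejected(self, small_torso):
        from voxdose.kernels import KernelLibrary
        dv, mv = small_torso
        cum = Volume(np.ones(dv.shape), 3.0)
        with pytest.raises(ValueError):
            dose_msv(cum, KernelLibrary({}), mv, dv)

    def test_medium_masks_partition_the_grid(self, msv_library, small_torso):
        dv, mv = small_torso
        mt = default_material_table()
        media = sorted(msv_library.kernels)
        dens = np.array([mt.material(m).density for m in media])
        mapped = np.array([
            media[int(np.argmin(np.abs(dens - mt.material(c).density)))]
            for c in range(13)])[mv.data.astype(int)]
        count = np.zeros(mv.shape, dtype=int)
        for m in media:
            count += (mapped == m).astype(int)
        assert np.all(count == 1)


class TestDoseSpecific:
    def test_zero_activity_gives_zero_dose(self, soft_kernel, small_torso):
        dv, mv = small_torso
        cum = Volume(np.zeros(dv.shape), 3.0)
        d = dose_specific(cum, SSVProvider(soft_kernel), dv, mv)
        assert np.all(d.data == 0)

    def test_ssv_provider_matches_convolution(self, soft_kernel,
                                              small_torso):
        dv, mv = small_torso
        rng = np.random.default_rng(5)
        cum = np.zeros(dv.shape)
        body = np.argwhere(mv.data > 0)
        picks = body[rng.choice(body.shape[0], 20, replace=False)]
        cum[tuple(picks.T)] = rng.random(20) * 10
        cumv = Volume(cum, 3.0)
        scatter = dose_specific(cumv, SSVProvider(soft_kernel), dv, mv,
                                reciprocity_correction=False)
        conv = dose_ssv(cumv, soft_kernel, dv)
        np.testing.assert_allclose(scatter.data, conv.data,
                                   rtol=1e-9, atol=1e-25)

    def test_air_sources_skipped(self, soft_kernel, small_torso):
        dv, mv = small_torso
        cum = np.zeros(dv.shape)
        cum[0, 0, 0] = 5.0  # air corner
        d = dose_specific(Volume(cum, 3.0), SSVProvider(soft_kernel), dv, mv)
        assert d.params["skipped_air_sources"] == 1
        assert np.all(d.data == 0)
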