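"""Monte Carlo engine: conservation, symmetry, scaling and oracle equivalence."""

import numpy as np
import pytest

from voxdose.constants import SOURCE_INDEX
from voxdose.dose import tally_to_gray
from voxdose.kernels import build_homogeneous_kernel, homogeneous_patch
from voxdose.materials import default_material_table
from voxdose.phantoms import CORTICAL_BONE, LUNG, SOFT_TISSUE
from voxdose.transport import (TransportResult, _run, estimate_uncertainty,
                               simulate_direct_dose, simulate_kernel,
                               simulate_point_source)
from voxdose.volumes import Volume


def _run_soft(n_hist, seed, boundary="vacuum", n_batches=10):
    patch = homogeneous_patch(SOFT_TISSUE)
    mats = Volume(np.full(patch.shape, SOFT_TISSUE, dtype=np.uint8), 3.0)
    return _run(patch, mats, n_hist, seed, n_batches, src_mode=0,
                source_index=SOURCE_INDEX, boundary=boundary)


class TestConservationAndContracts:
    @pytest.mark.parametrize("boundary", ["vacuum", "infinite"])
    def test_energy_conservation_per_batch(self, boundary):
        res = _run_soft(20_000, 3, boundary)
        deposited = res.analog_batches.sum(axis=(1, 2, 3))
        np.testing.assert_allclose(deposited + res.escaped_kev,
                                   res.emitted_kev, rtol=1e-12)

    def test_kerma_and_analog_totals_agree(self):
        res = _run_soft(50_000, 4)
        kerma = (res.kerma_batches + res.positron_batches).sum()
        analog = res.analog_batches.sum()
        assert kerma == pytest.approx(analog, rel=0.02)

    def test_all_air_patch_nearly_transparent(self):
        patch = homogeneous_patch(0)
        k = simulate_kernel(patch, 5000, 1, n_batches=2)
        emitted = 242.8 / 1000 + 1.022  # MeV per decay
        photon_mev = (k.deposition - k.positron_deposition).sum() * 0.027
        # photons barely interact in air; the slowing positron leaves a
        # small ionization trail before escaping
        assert photon_mev < 0.01 * 1.022
        assert k.total_energy_mev() < 0.05 * emitted

    def test_deposition_bounded_by_emission(self):
        res = _run_soft(20_000, 5)
        per_hist = res.analog_batches.sum() / res.histories
        assert per_hist <= 633.5 + 1022.0

    def test_same_seed_bit_identical(self):
        a = simulate_kernel(homogeneous_patch(SOFT_TISSUE), 5000, 11,
                            n_batches=2)
        b = simulate_kernel(homogeneous_patch(SOFT_TISSUE), 5000, 11,
                            n_batches=2)
        np.testing.assert_array_equal(a.deposition, b.deposition)

    def test_non_kernel_shapes_rejected(self):
        with pytest.raises(ValueError):
            simulate_kernel(Volume(np.ones((32, 32, 32)), 3.0), 5000, 1)
        with pytest.raises(ValueError):
            simulate_kernel(Volume(np.ones((64, 64, 64)), 2.0), 5000, 1)
        with pytest.raises(ValueError):
            simulate_kernel(homogeneous_patch(3), 100, 1)


class TestKernelPhysics:
    def test_maximum_at_source_voxel(self, soft_kernel):
        assert np.unravel_index(np.argmax(soft_kernel.deposition),
                                soft_kernel.shape) == SOURCE_INDEX

    def test_cubic_symmetry_of_homogeneous_kernel(self, soft_kernel):
        # voxels equidistant from the source along the axes form one orbit
        c = SOURCE_INDEX
        dep = soft_kernel.deposition
        unc = soft_kernel.uncertainty
        for d in (3, 8):
            orbit = [dep[c[0] + d, c[1], c[2]], dep[c[0] - d, c[1], c[2]],
                     dep[c[0], c[1] + d, c[2]], dep[c[0], c[1] - d, c[2]],
                     dep[c[0], c[1], c[2] + d], dep[c[0], c[1], c[2] - d]]
            sigma = [unc[c[0] + d, c[1], c[2]], unc[c[0] - d, c[1], c[2]],
                     unc[c[0], c[1] + d, c[2]], unc[c[0], c[1] - d, c[2]],
                     unc[c[0], c[1], c[2] + d], unc[c[0], c[1], c[2] - d]]
            mean = np.mean(orbit)
            for v, s in zip(orbit, sigma):
                assert abs(v - mean) <= 4 * s * v + 1e-12

    def test_total_energy_ordering_across_media(self, soft_kernel,
                                                lung_kernel,
                                                cortical_kernel):
        assert (lung_kernel.total_energy_mev()
                < soft_kernel.total_energy_mev()
                < cortical_kernel.total_energy_mev())

    def test_radial_decay_beyond_positron_shell(self, soft_kernel):
        idx = np.indices(soft_kernel.shape)
        r_cm = np.sqrt(sum((idx[a] - SOURCE_INDEX[a]) ** 2
                           for a in range(3))) * 0.3
        edges = np.arange(1.0, 9.0, 1.0)
        means = [soft_kernel.deposition[(r_cm >= lo) & (r_cm < lo + 1)].mean()
                 for lo in edges]
        assert np.all(np.diff(means) < 0)


class TestUncertainty:
    def test_duplicated_batches_zero_variance(self):
        grid = np.random.default_rng(0).random((1, 8, 8, 8))
        batches = np.repeat(grid, 4, axis=0)
        res = TransportResult(batches, np.zeros_like(batches),
                              batches, np.ones(4), np.zeros(4),
                              4000, 4, 0)
        rel = res.relative_uncertainty("photon")
        assert np.nanmax(rel) == 0

    def test_single_batch_errors(self):
        k = simulate_kernel(homogeneous_patch(SOFT_TISSUE), 2000, 1,
                            n_batches=1)
        with pytest.raises(ValueError):
            estimate_uncertainty(k)

    def test_one_over_sqrt_n_scaling(self):
        ns = [20_000, 80_000, 320_000]
        u = [estimate_uncertainty(
            build_homogeneous_kernel(SOFT_TISSUE, n, seed=21,
                                     boundary="vacuum"), radius_cm=6.0)
            for n in ns]
        for i in range(len(ns) - 1):
            expected = u[i] / 2.0  # 4x histories -> half the error
            assert u[i + 1] == pytest.approx(expected, rel=0.35)


class TestDirectDose:
    def test_delta_source_reproduces_kernel(self, small_torso):
        patch = homogeneous_patch(SOFT_TISSUE)
        cum = np.zeros(patch.shape)
        cum[SOURCE_INDEX] = 1.0
        dose = simulate_direct_dose(patch, Volume(cum, 3.0), 30_000, 9,
                                    n_batches=2)
        kernel = simulate_kernel(patch, 30_000, 10, n_batches=2,
                                 boundary="vacuum")
        want = tally_to_gray(kernel.deposition, 1.0, patch)
        # totals agree within statistical tolerance of two independent runs
        assert dose.data.sum() == pytest.approx(want.sum(), rel=0.05)

    def test_two_sources_superpose(self):
        mt = default_material_table()
        dens = np.full((24, 24, 24), mt.material(SOFT_TISSUE).density)
        vol = Volume(dens, 3.0)
        a = np.zeros(vol.shape)
        b = np.zeros(vol.shape)
        a[8, 12, 12] = 1.0
        b[16, 12, 12] = 1.0
        da = simulate_direct_dose(vol, Volume(a, 3.0), 40_000, 3,
                                  n_batches=2)
        db = simulate_direct_dose(vol, Volume(b, 3.0), 40_000, 4,
                                  n_batches=2)
        dab = simulate_direct_dose(vol, Volume(a + b, 3.0), 80_000, 5,
                                   n_batches=2)
        assert dab.data.sum() == pytest.approx(
            0.5 * (da.data.sum() + db.data.sum()) * 2, rel=0.05)

    def test_zero_activity_warns_and_returns_zero(self):
        vol = Volume(np.ones((8, 8, 8)), 3.0)
        with pytest.warns(UserWarning):
            d = simulate_direct_dose(vol, Volume(np.zeros((8, 8, 8)), 3.0),
                                     1000, 0)
        assert np.all(d.data == 0)

    def test_point_source_matches_direct_on_toy(self):
        mt = default_material_table()
        mats = np.full((16, 16, 16), SOFT_TISSUE, dtype=np.uint8)
        mats[:5] = LUNG
        mats[11:] = CORTICAL_BONE
        dens = mt.densities[mats]
        dv = Volume(dens, 3.0)
        mv = Volume(mats, 3.0)
        dep, _ = simulate_point_source(dv, (8, 8, 8), 40_000, 2,
                                       materials=mv, n_batches=2)
        cum = np.zeros(dv.shape)
        cum[8, 8, 8] = 1.0
        dose = simulate_direct_dose(dv, Volume(cum, 3.0), 40_000, 3,
                                    materials=mv, n_batches=2)
        want = tally_to_gray(dep, 1.0, dv)
        assert dose.data.sum() == pytest.approx(want.sum(), rel=0.05)
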