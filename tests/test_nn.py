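"""Learned kernel predictor: normalization, architecture, training, inference."""

import numpy as np
import pytest

from voxdose import nn
from voxdose.dose import dose_specific
from voxdose.kernels import homogeneous_patch
from voxdose.phantoms import LUNG, SOFT_TISSUE
from voxdose.volumes import Volume


@pytest.fixture(scope="module")
def tiny_pairs(request):
    """A handful of (patch, kernel) pairs from the two homogeneous media."""
    soft_kernel = request.getfixturevalue("soft_kernel")
    lung_kernel = request.getfixturevalue("lung_kernel")
    return [(homogeneous_patch(SOFT_TISSUE), soft_kernel),
            (homogeneous_patch(LUNG), lung_kernel)] * 5


@pytest.fixture(scope="module")
def tiny_model(tiny_pairs):
    model, history = nn.train(
        tiny_pairs, nn.ModelSpec(channels=2),
        nn.TrainSpec(epochs=3, crop=16, batch_size=4, seed=1))
    return model, history


class TestNormalization:
    def test_round_trip_inverse(self, soft_kernel):
        spec = nn.NormalizationSpec.fit([soft_kernel])
        y = nn.normalize_kernel(soft_kernel.deposition, spec)
        back = nn.denormalize_kernel(y, spec)
        nz = soft_kernel.deposition > 0
        rel = np.abs(back[nz] - soft_kernel.deposition[nz]) \
            / soft_kernel.deposition[nz]
        assert rel.max() < 1e-6

    def test_output_in_unit_interval(self, soft_kernel):
        spec = nn.NormalizationSpec.fit([soft_kernel])
        y = nn.normalize_kernel(soft_kernel.deposition, spec)
        assert y.min() > 0 and y.max() < 1

    def test_order_preserved(self):
        spec = nn.NormalizationSpec(center=-10.0, scale=2.0, floor=1e-12)
        a = np.array([1e-6, 1e-4, 1e-2])
        y = nn.normalize_kernel(a, spec)
        assert np.all(np.diff(y) > 0)

    def test_negative_deposition_rejected(self):
        spec = nn.NormalizationSpec(center=0.0, scale=1.0)
        with pytest.raises(ValueError):
            nn.normalize_kernel(np.array([-1.0]), spec)


class TestArchitecture:
    def test_layer_and_block_counts(self):
        net = nn.DilatedResNet(nn.ModelSpec(channels=2), seed=0)
        assert net.n_layers == 20
        assert net.spec.n_residual_blocks == 9

    def test_dilation_schedule(self):
        spec = nn.ModelSpec()
        assert spec.dilations[:7] == (1,) * 7
        assert spec.dilations[7:14] == (2,) * 7
        assert spec.dilations[14:] == (4,) * 6

    def test_parameter_count_formula(self):
        c = 3
        net = nn.DilatedResNet(nn.ModelSpec(channels=c), seed=0)
        want = (27 * 1 * c + c) + 18 * (27 * c * c + c) + (27 * c * 1 + 1)
        assert net.parameter_count() == want

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            nn.ModelSpec(n_layers=10)
        with pytest.raises(ValueError):
            nn.ModelSpec(n_residual_blocks=8)

    def test_gradient_check_single_conv(self):
        # finite-difference check of the conv backward pass (float32
        # compute, hence the loose step and tolerance)
        rng = np.random.default_rng(0)
        conv = nn._Conv3d(2, 2, dilation=2, rng=rng)
        x = rng.normal(size=(1, 2, 6, 6, 6)).astype(np.float32)
        y = conv.forward(x)
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = conv.backward(dy)
        eps = 1e-2
        for idx in [(0, 0, 2, 3, 1), (0, 1, 5, 0, 4)]:
            xp = x.copy()
            xm = x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(conv.forward(xp, keep=False) * dy, dtype=np.float64)
                   - np.sum(conv.forward(xm, keep=False) * dy,
                            dtype=np.float64)) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=2e-2, abs=1e-3)
        widx = (13, 1, 0)
        wp = conv.w[widx]
        conv.w[widx] = wp + eps
        up = np.sum(conv.forward(x, keep=False) * dy, dtype=np.float64)
        conv.w[widx] = wp - eps
        dn = np.sum(conv.forward(x, keep=False) * dy, dtype=np.float64)
        conv.w[widx] = wp
        assert (up - dn) / (2 * eps) == pytest.approx(conv.dw[widx],
                                                      rel=2e-2)


class TestTraining:
    def test_loss_decreases_on_memorization(self, tiny_model):
        _, history = tiny_model
        assert history[-1] < history[0]

    def test_validation_loss_improves(self, tiny_model):
        model, _ = tiny_model
        v0, v1 = model.val_loss
        assert v1 < v0

    def test_reproducible_for_fixed_seed(self, tiny_pairs):
        spec = nn.TrainSpec(epochs=1, crop=8, batch_size=4, seed=3)
        _, h1 = nn.train(tiny_pairs, nn.ModelSpec(channels=2), spec)
        _, h2 = nn.train(tiny_pairs, nn.ModelSpec(channels=2), spec)
        np.testing.assert_array_equal(h1, h2)

    def test_shape_mismatch_rejected(self, soft_kernel):
        bad = Volume(np.ones((32, 32, 32)), 3.0)
        with pytest.raises(ValueError):
            nn.train([(bad, soft_kernel)] * 4)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            nn.train([])


class TestInference:
    def test_prediction_contract(self, tiny_model):
        model, _ = tiny_model
        pred = nn.predict(model, homogeneous_patch(SOFT_TISSUE))
        assert pred.shape == (64, 64, 64)
        assert pred.source_index == (32, 32, 32)
        assert pred.provenance == "learned"
        assert np.all(pred.deposition >= 0)

    def test_inference_deterministic(self, tiny_model):
        model, _ = tiny_model
        patch = homogeneous_patch(LUNG)
        a = nn.predict(model, patch)
        b = nn.predict(model, patch)
        np.testing.assert_array_equal(a.deposition, b.deposition)

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            nn.predict(None, homogeneous_patch(SOFT_TISSUE))
        with pytest.raises(ValueError):
            nn.LearnedKernelProvider().kernel_for(
                homogeneous_patch(SOFT_TISSUE))

    def test_save_load_round_trip(self, tiny_model, tmp_path):
        model, _ = tiny_model
        path = tmp_path / "model.npz"
        nn.save_model(model, path)
        back = nn.load_model(path)
        patch = homogeneous_patch(SOFT_TISSUE)
        np.testing.assert_array_equal(nn.predict(model, patch).deposition,
                                      nn.predict(back, patch).deposition)

    def test_learned_provider_plugs_into_dose_engine(self, tiny_model,
                                                     small_torso):
        model, _ = tiny_model
        dv, mv = small_torso
        cum = np.zeros(dv.shape)
        src = tuple(np.argwhere(mv.data == SOFT_TISSUE)[0])
        cum[src] = 1.0
        provider = nn.LearnedKernelProvider(model=model)
        d = dose_specific(Volume(cum, 3.0), provider, dv, mv)
        assert d.data.max() > 0
        assert d.params["provider"] == "learned"
        assert d.params["reciprocity_correction"] is True
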