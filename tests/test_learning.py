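"""Encoder, channel matching, manual backprop, and the two training steps."""

import numpy as np
import pytest

from cret.decoder import BasisConfig, ProjectionPlan
from cret.experiment import default_geometry
from cret.learning import (CRETModel, EncoderSpec, TrainConfig, build_dataset,
                           channel_match, channel_match_backward, encode,
                           gt_patch, train_step1, _step1_forward_backward)
from cret.nn import Adam, Restorator, TinyEncoder, conv2d, conv2d_backward, l1_loss
from cret.phantoms import make_phantom
from cret.squeeze import ROISpec


@pytest.fixture(scope="module")
def tiny_dataset():
    g = default_geometry(n_views=60)
    ph = make_phantom("random_ellipses", 96, 0.7, 3)
    return build_dataset([ph], g, scales=(2,), patch_extent=22.4,
                         out_resolution=32, seed=1, n_centers=1)


class TestConvBackprop:
    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 6, 7))
        w = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        dy = rng.normal(size=(3, 6, 7))
        dx, dw, db = conv2d_backward(dy, x, w)
        eps = 1e-6
        for arr, grad in ((x, dx), (w, dw), (b, db)):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = np.vdot(conv2d(x, w, b), dy)
            arr[idx] = orig - eps
            lm = np.vdot(conv2d(x, w, b), dy)
            arr[idx] = orig
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


class TestEncode:
    def test_identity_like_determinism(self, tiny_dataset):
        model = CRETModel.create(EncoderSpec(seed=4))
        roi = ROISpec(tiny_dataset.centers[0][0], 22.4, 32, binning=2)
        sq = model.squeeze_for(tiny_dataset.filtered[(0, 2)], roi)
        f1 = encode(sq, model.encoder)
        f2 = encode(sq, model.encoder)
        assert f1.shape == (32,) + sq.data.shape[:2]
        assert np.array_equal(f1, f2)  # bitwise stable

    def test_channel_layout_enforced(self, tiny_dataset):
        enc_plain = TinyEncoder(unfolded=False)
        model = CRETModel.create(EncoderSpec(seed=0))
        roi = ROISpec(tiny_dataset.centers[0][0], 22.4, 32, binning=2)
        sq = model.squeeze_for(tiny_dataset.filtered[(0, 2)], roi)  # unfolded
        with pytest.raises(ValueError, match="nine-channel"):
            encode(sq, enc_plain)


class TestChannelMatch:
    def test_zero_and_identity_gamma(self):
        basis = BasisConfig(5)
        feats = np.random.default_rng(0).normal(size=(32, 6, 8))
        z0 = channel_match(feats, np.zeros((11, 32)), basis)
        assert np.array_equal(z0.data, np.zeros((6, 8, 11)))
        gamma = np.zeros((11, 32))
        gamma[:, :11] = np.eye(11)
        zi = channel_match(feats, gamma, basis)
        assert np.array_equal(zi.data, feats[:11].transpose(1, 2, 0))

    def test_linear_and_adjoint(self):
        basis = BasisConfig(2)
        rng = np.random.default_rng(1)
        fa, fb = rng.normal(size=(2, 4, 3, 5))
        gamma = rng.normal(size=(basis.dim, 4))
        out = channel_match(2 * fa - fb, gamma, basis).data
        assert np.allclose(out, 2 * channel_match(fa, gamma, basis).data
                           - channel_match(fb, gamma, basis).data)
        gz = rng.normal(size=out.shape)
        dfeat, dgamma = channel_match_backward(gz, fa, gamma)
        inner = np.vdot(channel_match(fa, gamma, basis).data, gz)
        assert inner == pytest.approx(np.vdot(fa, dfeat), rel=1e-12)
        assert inner == pytest.approx(np.vdot(gamma, dgamma), rel=1e-12)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            channel_match(np.zeros((32, 4, 4)), np.zeros((10, 32)), BasisConfig(5))


class TestTrainingStep1:
    def test_initial_loss_equals_fbp_error(self, tiny_dataset):
        # gamma starts at zero, so the first forward pass is exactly FBP
        model = CRETModel.create(EncoderSpec(seed=0))
        center = tiny_dataset.centers[0][0]
        roi = ROISpec(center, 22.4, 32, binning=2)
        z = tiny_dataset.filtered[(0, 2)]
        sq = model.squeeze_for(z, roi)
        plan = ProjectionPlan(sq, roi.grid)
        target = gt_patch(tiny_dataset.phantoms[0], roi)
        loss, _ = _step1_forward_backward(model, sq, plan, target)
        fbp_err = float(np.mean(np.abs(model.fbp_roi(z, roi).data - target)))
        assert loss == pytest.approx(fbp_err, rel=1e-12)

    def test_overfit_single_roi(self, tiny_dataset):
        # 200 iterations on one phantom / one ROI cut the L1 loss by >= 50%
        cfg = TrainConfig(epochs=10, iters_per_epoch=20, batch_size=1,
                          lr=2e-3, seed=0)
        model, hist = train_step1(tiny_dataset, cfg)
        assert hist[-1]["loss"] <= 0.5 * hist[0]["first_iter_loss"]

    def test_gamma_gradient_matches_finite_differences(self, tiny_dataset):
        model = CRETModel.create(EncoderSpec(seed=0))
        center = tiny_dataset.centers[0][0]
        roi = ROISpec(center, 22.4, 8, binning=2)
        sq = model.squeeze_for(tiny_dataset.filtered[(0, 2)], roi)
        plan = ProjectionPlan(sq, roi.grid)
        target = gt_patch(tiny_dataset.phantoms[0], roi)
        rng = np.random.default_rng(0)
        model.gamma[:] = rng.normal(0, 0.01, model.gamma.shape)
        _, dgamma = _step1_forward_backward(model, sq, plan, target)
        eps = 1e-5
        for idx in [(0, 0), (3, 7), (10, 31)]:
            orig = model.gamma[idx]
            model.gamma[idx] = orig + eps
            lp, _ = _step1_forward_backward(model, sq, plan, target)
            model.gamma[idx] = orig - eps
            lm, _ = _step1_forward_backward(model, sq, plan, target)
            model.gamma[idx] = orig
            assert dgamma[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)

    def test_checkpoint_roundtrip_bitwise(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=1, iters_per_epoch=3, batch_size=1, lr=1e-3, seed=0)
        model, _ = train_step1(tiny_dataset, cfg,
                               checkpoint_path=tmp_path / "ckpt.npz")
        loaded = CRETModel.load(tmp_path / "ckpt.npz")
        roi = ROISpec(tiny_dataset.centers[0][0], 22.4, 32, binning=2)
        z = tiny_dataset.filtered[(0, 2)]
        assert np.array_equal(model.reconstruct(z, roi).data,
                              loaded.reconstruct(z, roi).data)


class TestRestorator:
    def test_identity_at_init(self):
        rest = Restorator(seed=0)
        x = np.random.default_rng(0).normal(size=(1, 12, 12))
        assert np.array_equal(rest(x), x)  # zero-init last layer => identity

    def test_backprop_matches_finite_differences(self):
        rest = Restorator(hidden=4, seed=1)
        rng = np.random.default_rng(2)
        # give the last layer weight so gradients reach every layer
        rest.layers["conv6"].weight = rng.normal(0, 0.1,
                                                 rest.layers["conv6"].weight.shape)
        x = rng.normal(size=(1, 8, 8))
        target = rng.normal(size=(1, 8, 8))
        y, cache = rest.forward(x)
        loss, dy = l1_loss(y, target)
        rest.backward(dy, cache)
        w = rest.layers["conv3"].weight
        g = rest.grads["conv3.weight"]
        idx = (1, 2, 0, 1)
        eps = 1e-6
        orig = w[idx]
        w[idx] = orig + eps
        lp, _ = l1_loss(rest(x), target)
        w[idx] = orig - eps
        lm, _ = l1_loss(rest(x), target)
        w[idx] = orig
        assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)


class TestAdam:
    def test_converges_on_quadratic(self):
        p = [np.array([5.0, -3.0])]
        opt = Adam(p, lr=0.1)
        for _ in range(500):
            opt.step([2.0 * p[0]])
        assert np.abs(p[0]).max() < 1e-3

    def test_lr_schedule_halves_at_milestones(self):
        cfg = TrainConfig(epochs=10, lr=1e-3, decay_at=(0.2, 0.4, 0.6, 0.8))
        lrs = [cfg.lr_at(e) for e in range(10)]
        assert lrs[0] == 1e-3 and lrs[1] == 1e-3
        assert lrs[2] == 5e-4          # halved at 0.2 * 10
        assert lrs[4] == 2.5e-4
        assert lrs[8] == 1e-3 * 0.5**4


class TestDeskScaleStudy:
    """Properties of the shared desk-scale study (see conftest)."""

    def test_cret_beats_fbp_on_held_out_in_scale(self, study):
        rep = study["report"]
        assert rep.mean("cret", 2) > rep.mean("fbp", 2)
        assert rep.mean("cret", 4) > rep.mean("fbp", 4)

    def test_restorator_helps_at_high_binning(self, study):
        rep = study["report"]
        assert rep.mean("cret+", 4) >= rep.mean("cret", 4)

    def test_restorator_is_plug_and_play(self, study, tiny_dataset):
        # disabling the restorator leaves the step-1 output untouched
        model = study["model"]
        roi = ROISpec(tiny_dataset.centers[0][0], 22.4, 32, binning=2)
        z = tiny_dataset.filtered[(0, 2)]
        base = model.reconstruct(z, roi).data
        restored = model.reconstruct(z, roi, restore=True).data
        again = model.reconstruct(z, roi).data
        assert np.array_equal(base, again)
        assert not np.array_equal(base, restored)
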