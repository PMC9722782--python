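"""Autograd primitives (finite-difference checks) and the residual U-Net."""

import numpy as np
import pytest

from gliofed import nn
from gliofed.model import (
    AdamState,
    ModelConfig,
    ResUNet3D,
    expected_n_parameters,
    init_model,
    tiny_config,
)


def numeric_grad(f, arrs, i, idx, eps=1e-6):
    ap = [a.copy() for a in arrs]
    am = [a.copy() for a in arrs]
    ap[i][idx] += eps
    am[i][idx] -= eps
    return (f(ap) - f(am)) / (2 * eps)


class TestAutogradGradients:
    """Analytic pullbacks agree with central finite differences (float64)."""

    def _check(self, build, arrs, rng, tol=1e-6):
        def value(xs):
            out, _ = build(xs)
            return float(out.data.sum())

        out, tensors = build(arrs)
        nn.backward(out, seed_grad=np.ones_like(out.data))
        for i, (a, t) in enumerate(zip(arrs, tensors)):
            idx = tuple(rng.integers(0, s) for s in a.shape)
            num = numeric_grad(value, arrs, i, idx)
            ana = t.grad[idx]
            assert ana == pytest.approx(num, abs=tol, rel=1e-4), f"input {i}"

    def test_conv3d(self, rng):
        x = rng.normal(size=(2, 6, 6, 6))
        w = rng.normal(size=(3, 2, 3, 3, 3))
        b = rng.normal(size=3)

        def build(arrs):
            ts = [nn.param(a) for a in arrs]
            return nn.conv3d(ts[0], ts[1], ts[2], pad=1), ts

        self._check(build, [x, w, b], rng)

    def test_conv3d_stride2(self, rng):
        x = rng.normal(size=(2, 8, 8, 8))
        w = rng.normal(size=(4, 2, 3, 3, 3))
        b = rng.normal(size=4)

        def build(arrs):
            ts = [nn.param(a) for a in arrs]
            return nn.conv3d(ts[0], ts[1], ts[2], stride=2, pad=1), ts

        self._check(build, [x, w, b], rng)

    def test_conv_transpose2(self, rng):
        x = rng.normal(size=(3, 4, 4, 4))
        w = rng.normal(size=(3, 2, 2, 2, 2))
        b = rng.normal(size=2)

        def build(arrs):
            ts = [nn.param(a) for a in arrs]
            return nn.conv_transpose2(ts[0], ts[1], ts[2]), ts

        self._check(build, [x, w, b], rng)

    def test_instance_norm(self, rng):
        x = rng.normal(size=(3, 5, 5, 5))
        g = rng.normal(size=3) + 1.0
        b = rng.normal(size=3)

        def build(arrs):
            ts = [nn.param(a) for a in arrs]
            # sum-of-squares head makes the pullback nontrivial
            out = nn.instance_norm(ts[0], ts[1], ts[2])
            return nn.sigmoid(out), ts

        self._check(build, [x, g, b], rng)

    def test_mirrored_loss_gradient(self, rng):
        ref = (rng.random((3, 4, 4, 4)) > 0.6).astype(float)
        x = rng.normal(size=(3, 4, 4, 4))

        def build(arrs):
            ts = [nn.param(a) for a in arrs]
            return nn.mirrored_soft_dice_loss(nn.sigmoid(ts[0]), ref), ts

        self._check(build, [x], rng)


class TestInitModel:
    def test_same_seed_bit_identical(self):
        cfg = tiny_config(seed=9)
        a, b = init_model(cfg), init_model(cfg)
        assert a.arrays.keys() == b.arrays.keys()
        assert all(np.array_equal(a.arrays[k], b.arrays[k]) for k in a.arrays)

    def test_more_filters_more_parameters(self):
        small = init_model(tiny_config(base_filters=4))
        big = init_model(tiny_config(base_filters=8))
        assert big.n_parameters() > small.n_parameters()

    @pytest.mark.parametrize("filters, depth", [(2, 1), (4, 2), (3, 2)])
    def test_parameter_count_matches_tally(self, filters, depth):
        """Actual parameter count equals a layer-by-layer arithmetic tally."""
        cfg = tiny_config(base_filters=filters, depth=depth, patch_size=8)
        assert init_model(cfg).n_parameters() == expected_n_parameters(cfg)

    def test_incompatible_patch_depth_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(base_filters=2, depth=3, patch_size=12)


@pytest.fixture(scope="module")
def net():
    return ResUNet3D(tiny_config(base_filters=2, seed=1))


class TestForward:
    def test_shape_preserving_three_channels(self, net, rng):
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        out = net.forward(x)
        assert out.kind == "sigmoid"
        assert out.channels.shape == (3, 16, 16, 16)

    def test_values_in_open_unit_interval(self, net, rng):
        out = net.forward(rng.normal(size=(4, 16, 16, 16)).astype(np.float32))
        assert np.all(out.channels > 0) and np.all(out.channels < 1)

    def test_deterministic(self, net, rng):
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(net.forward(x).channels, net.forward(x).channels)

    def test_wrong_channel_count_rejected(self, net, rng):
        with pytest.raises(ValueError, match="4, D, H, W"):
            net.forward(rng.normal(size=(3, 16, 16, 16)))

    def test_volume_inference_unpads_exactly(self, net, rng):
        x = rng.normal(size=(4, 13, 15, 10)).astype(np.float32)
        out = net.predict_volume(x)
        assert out.channels.shape == (3, 13, 15, 10)


class TestTraining:
    def test_lr_zero_leaves_params_unchanged(self, rng):
        net = ResUNet3D(tiny_config(base_filters=2, lr=0.0))
        before = net.params.copy()
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        ref = (rng.random((3, 16, 16, 16)) > 0.5).astype(np.float32)
        net.train_step(AdamState.for_params(net.params), x, ref)
        assert all(np.array_equal(before.arrays[k], net.params.arrays[k])
                   for k in before.arrays)

    def test_epoch_loss_is_mean_of_steps(self, two_site_dataset, aug_cfg):
        """Logged epoch loss equals the mean of per-case losses, via an
        independent accumulation at lr=0 (same model state per step)."""
        from gliofed.model import train_local_epoch
        from gliofed.preprocess import augment, sample_patch

        cases = two_site_dataset.sites[0].train_cases
        net = ResUNet3D(tiny_config(base_filters=2, lr=0.0, seed=4))
        opt = AdamState.for_params(net.params)
        mean_loss = train_local_epoch(net, opt, cases, aug_cfg, np.random.default_rng(5))
        # replay the identical stream by hand
        from gliofed.metrics import mirrored_dsc_loss

        rng = np.random.default_rng(5)
        order = rng.permutation(len(cases))
        losses = []
        for idx in order:
            pp = sample_patch(cases[idx].image, cases[idx].labels, net.cfg.patch_size, rng)
            pp = augment(pp, aug_cfg, rng)
            losses.append(mirrored_dsc_loss(pp.reference, net.forward(pp.image)))
        assert mean_loss == pytest.approx(float(np.mean(losses)), abs=1e-5)

    def test_training_reduces_loss_on_phantoms(self, two_site_dataset, aug_cfg):
        """Mean loss after 20 local epochs is below the first epoch's."""
        from gliofed.model import train_local_epoch

        cases = two_site_dataset.sites[0].train_cases
        net = ResUNet3D(tiny_config(seed=2))
        opt = AdamState.for_params(net.params)
        first = train_local_epoch(net, opt, cases, aug_cfg, np.random.default_rng(10))
        last = None
        for ep in range(1, 20):
            last = train_local_epoch(net, opt, cases, aug_cfg, np.random.default_rng(10 + ep))
        assert last < first
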