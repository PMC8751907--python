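"""Network engine: gradients, shape contracts, losses, training mechanics."""

import numpy as np
import pytest

from vregnet3d.networks import (
    RegressionNetConfig, SegmentationNetConfig, TrainingConfig,
    build_regression_net, build_segmentation_net,
    dice_loss, dice_loss_with_grad,
    scaled_mse_loss, scaled_mse_loss_with_grad,
    sample_patch, augment_patch, predict_tiled, train,
)
from vregnet3d.networks.layers import Conv3D, ConvTranspose3D
from vregnet3d.networks.training import AUGMENT_OPS, _apply_op, early_stop_epoch


class TestArchitecture:
    def test_regression_output_shape_matches_input(self):
        net = build_regression_net(
            RegressionNetConfig(n_levels=3, base_channels=2), seed=0)
        x = np.random.default_rng(0).normal(size=(1, 1, 64, 64, 32))
        y = net.forward(x)
        assert y.shape == (1, 1, 64, 64, 32)

    def test_transposed_conv_exactly_doubles(self):
        rng = np.random.default_rng(1)
        layer = ConvTranspose3D(1, 1, 5, rng)
        x = rng.normal(size=(1, 1, 8, 8, 8))
        assert layer.forward(x).shape == (1, 1, 16, 16, 16)

    def test_same_seed_identical_parameters(self):
        a = build_regression_net(seed=7)
        b = build_regression_net(seed=7)
        for k in a.parameters():
            np.testing.assert_array_equal(a.get_param(k), b.get_param(k))
        sa = build_segmentation_net(2, seed=7)
        sb = build_segmentation_net(2, seed=7)
        for k in sa.parameters():
            np.testing.assert_array_equal(sa.get_param(k), sb.get_param(k))

    def test_indivisible_shape_raises(self):
        net = build_regression_net(
            RegressionNetConfig(n_levels=3, base_channels=2), seed=0)
        with pytest.raises(ValueError, match="multiples"):
            net.forward(np.zeros((1, 1, 20, 20, 20)))

    def test_segmentation_softmax_normalized(self):
        net = build_segmentation_net(
            2, SegmentationNetConfig(n_levels=2, base_channels=2), seed=3)
        x = np.random.default_rng(3).normal(size=(1, 1, 16, 16, 8))
        p = net.forward(x)
        assert p.shape == (1, 2, 16, 16, 8)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_segmentation_three_class_channels(self):
        net = build_segmentation_net(
            3, SegmentationNetConfig(n_levels=2, base_channels=2), seed=3)
        x = np.random.default_rng(3).normal(size=(1, 1, 16, 16, 8))
        assert net.forward(x).shape == (1, 3, 16, 16, 8)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            build_segmentation_net(4, seed=0)


class TestGradients:
    """Analytic backward passes agree with central finite differences."""

    @pytest.mark.parametrize("kernel", [1, 5])
    def test_conv_gradients(self, kernel, rng):
        layer = Conv3D(2, 3, kernel, rng)
        x = rng.normal(size=(1, 2, 6, 6, 4))
        g = rng.normal(size=(1, 3, 6, 6, 4))
        layer.forward(x)
        dx = layer.backward(g)
        eps = 1e-6
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(g * layer.forward(xp))
                   - np.sum(g * layer.forward(xm))) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=1e-5, abs=1e-8)
        layer.forward(x)
        layer.backward(g)
        w = layer.params["w"]
        dw = layer.grads["w"]
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in w.shape)
            orig = w[idx]
            w[idx] = orig + eps
            lp = np.sum(g * layer.forward(x))
            w[idx] = orig - eps
            lm = np.sum(g * layer.forward(x))
            w[idx] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(dw[idx], rel=1e-5)

    def test_end_to_end_regression_gradient(self, rng):
        net = build_regression_net(
            RegressionNetConfig(n_levels=2, base_channels=2,
                                dropout_rate=0.0), seed=1)
        x = rng.normal(size=(1, 1, 8, 8, 4))
        t = rng.random((1, 1, 8, 8, 4)) * 0.1
        _, grad = scaled_mse_loss_with_grad(net.forward(x, training=True),
                                            t, 10.0)
        net.backward(grad)
        key = list(net.parameters())[0]
        w, gw = net.get_param(key), net.get_grad(key)
        idx = tuple(rng.integers(0, s) for s in w.shape)
        eps, orig = 1e-6, w[idx]
        w[idx] = orig + eps
        lp = scaled_mse_loss(net.forward(x, training=True), t, 10.0)
        w[idx] = orig - eps
        lm = scaled_mse_loss(net.forward(x, training=True), t, 10.0)
        w[idx] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(gw[idx], rel=1e-4)


class TestLosses:
    def test_dice_zero_at_one_hot_equality(self):
        t = np.zeros((2, 4, 4, 4))
        t[1, :2] = 1.0
        t[0] = 1.0 - t[1]
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_dice_one_for_disjoint_supports(self):
        p = np.zeros((2, 4, 4, 4))
        t = np.zeros((2, 4, 4, 4))
        p[0] = 1.0
        t[1] = 1.0
        assert dice_loss(p, t) == pytest.approx(1.0, abs=1e-6)

    def test_dice_uniform_half_prediction_hand_summation(self):
        """Uniform 0.5 prediction on a half-foreground toy volume.

        Direct summation per class: intersection = 0.5 * N/2 = N/4,
        denominator = sum(p^2) + sum(t^2) = N/4 + N/2 = 3N/4, so Dice
        = 2*(N/4)/(3N/4) = 2/3 for both classes and the loss is 1/3.
        """
        n = 4 * 4 * 4
        t = np.zeros((2, 4, 4, 4))
        t[1, :2] = 1.0
        t[0] = 1.0 - t[1]
        p = np.full((2, 4, 4, 4), 0.5)
        expected = 1.0 - (2.0 * (n / 4) / (n / 4 + n / 2))
        assert dice_loss(p, t) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(1.0 / 3.0)

    def test_scaled_mse_zero_at_scaled_equality(self):
        t = np.random.default_rng(0).random((1, 6, 6, 6))
        assert scaled_mse_loss(10000.0 * t, t) == pytest.approx(0.0)

    def test_scaled_mse_single_peak_arithmetic(self):
        t = np.zeros((1, 5, 5, 4))
        t[0, 2, 2, 2] = 1.0
        n = t.size
        assert scaled_mse_loss(np.zeros_like(t), t, scale=100.0) == \
            pytest.approx(100.0 ** 2 / n)

    def test_mse_invariant_under_joint_permutation(self, rng):
        p = rng.random((1, 4, 4, 4))
        t = rng.random((1, 4, 4, 4))
        perm = rng.permutation(p.size)
        lp = scaled_mse_loss(p, t, 7.0)
        lq = scaled_mse_loss(p.ravel()[perm].reshape(p.shape),
                             t.ravel()[perm].reshape(t.shape), 7.0)
        assert lp == pytest.approx(lq)

    def test_losses_nonnegative(self, rng):
        p = rng.random((2, 4, 4, 4))
        p /= p.sum(axis=0, keepdims=True)
        t = np.zeros_like(p)
        t[0] = 1.0
        assert dice_loss(p, t) >= 0.0
        assert scaled_mse_loss(rng.normal(size=(4, 4, 4)),
                               rng.random((4, 4, 4))) >= 0.0


class TestAugmentation:
    def test_reflection_is_involution(self, rng):
        x = rng.random((2, 4, 4, 3))
        np.testing.assert_array_equal(
            _apply_op(_apply_op(x, "reflect_x"), "reflect_x"), x)

    def test_four_rotations_identity(self, rng):
        x = rng.random((2, 4, 4, 3))
        y = x
        for _ in range(4):
            y = _apply_op(y, "rot90_z")
        np.testing.assert_array_equal(y, x)

    def test_value_multiset_preserved(self, rng):
        x = rng.random((1, 4, 4, 3))
        for op in AUGMENT_OPS:
            y = _apply_op(x, op)
            np.testing.assert_array_equal(np.sort(y.ravel()),
                                          np.sort(x.ravel()))

    def test_image_and_target_get_same_op(self, rng):
        x = np.arange(64, dtype=float).reshape(1, 4, 4, 4)
        xa, ya = augment_patch(x, x.copy(), np.random.default_rng(12))
        np.testing.assert_array_equal(xa, ya)


class TestPatchSampling:
    def test_patch_equal_to_volume(self, rng):
        vol = rng.random((8, 8, 8))
        origin, patch = sample_patch(vol, (8, 8, 8), rng)
        assert origin == (0, 0, 0)
        np.testing.assert_array_equal(patch, vol)

    def test_origin_distribution_uniform(self):
        """10^4 draws of a 1^3 patch in a 4^3 volume: each of the 64 origins
        appears within 4 s.e. of the uniform expectation."""
        rng = np.random.default_rng(5)
        vol = np.zeros((4, 4, 4))
        counts = np.zeros((4, 4, 4))
        n = 10_000
        for _ in range(n):
            o, _ = sample_patch(vol, (1, 1, 1), rng)
            counts[o] += 1
        p = 1.0 / 64
        se = np.sqrt(n * p * (1 - p))
        assert np.abs(counts - n * p).max() <= 4 * se

    def test_fixed_seed_reproducible(self, rng):
        vol = np.arange(5 ** 3, dtype=float).reshape(5, 5, 5)
        o1, _ = sample_patch(vol, (2, 2, 2), np.random.default_rng(9))
        o2, _ = sample_patch(vol, (2, 2, 2), np.random.default_rng(9))
        assert o1 == o2

    def test_oversized_patch_raises(self, rng):
        with pytest.raises(ValueError, match="larger"):
            sample_patch(np.zeros((4, 4, 4)), (8, 4, 4), rng)


class TestTrainingLoop:
    def test_early_stop_forced_sequence(self):
        """Validation sequence [3,2,2,2,2]: no decrease after epoch 1, so
        training stops after the third non-improving epoch (index 4)."""
        assert early_stop_epoch([3, 2, 2, 2, 2], patience_no_decrease=2) == 4

    def test_early_stop_on_consecutive_increase(self):
        assert early_stop_epoch([3, 2, 2.5, 2.6], stop_on_increase=1) == 3

    def test_no_stop_when_improving(self):
        assert early_stop_epoch([3, 2.5, 2, 1.5, 1]) is None

    def test_lr_drop_schedule_arithmetic(self):
        """After one drop period the learning rate is initial * factor."""
        rng = np.random.default_rng(0)
        net = build_regression_net(
            RegressionNetConfig(n_levels=1, base_channels=2,
                                dropout_rate=0.0), seed=0)
        vol = rng.random((8, 8, 4))
        tgt = rng.random((8, 8, 4)) * 0.01
        cfg = TrainingConfig(initial_lr=1e-3, lr_drop_factor=0.5,
                             lr_drop_period_epochs=2, minibatch_size=1,
                             patch_size_voxels=(8, 8, 4), patches_per_epoch=1,
                             max_epochs=4, augment=False, seed=0)
        res = train(net, vol, tgt, cfg,
                    lambda p, t: scaled_mse_loss_with_grad(p, t, 1.0))
        assert res.lr_schedule[:4] == [1e-3, 1e-3, 5e-4, 5e-4]

    def test_smoke_training_reduces_loss(self):
        """A tiny overfit run must lower the training loss."""
        rng = np.random.default_rng(3)
        vol = np.zeros((8, 8, 8))
        vol[2:6, 2:6, 2:6] = 1.0
        tgt = vol * 0.5
        net = build_regression_net(
            RegressionNetConfig(n_levels=1, base_channels=4,
                                dropout_rate=0.0), seed=2)
        cfg = TrainingConfig(initial_lr=1e-2, minibatch_size=1,
                             patch_size_voxels=(8, 8, 8), patches_per_epoch=4,
                             max_epochs=5, augment=False,
                             patience_no_decrease=10, stop_on_increase=10,
                             seed=1)
        res = train(net, vol, tgt, cfg,
                    lambda p, t: scaled_mse_loss_with_grad(p, t, 1.0))
        assert res.train_loss[-1] < res.train_loss[0]


class TestTiledPrediction:
    def _net(self):
        return build_regression_net(
            RegressionNetConfig(n_levels=2, base_channels=2,
                                dropout_rate=0.0), seed=4)

    def test_constant_volume_translation_equivariant(self):
        """On constant input every tile responds identically, so disjoint
        tiles of the blended output are equal (zero-padding makes the
        response vary *within* a tile, but not between tiles)."""
        net = self._net()
        vol = np.full((16, 16, 8), 0.3)
        out = predict_tiled(net, vol, (8, 8, 4), overlap=(0, 0, 0))
        np.testing.assert_allclose(out[:, :8, :8, :4], out[:, 8:, 8:, 4:],
                                   atol=1e-12)

    def test_single_patch_equals_direct(self, rng):
        net = self._net()
        vol = rng.random((8, 8, 8))
        tiled = predict_tiled(net, vol, (8, 8, 8), overlap=(0, 0, 0))
        direct = net.predict(vol)
        np.testing.assert_allclose(tiled, direct, atol=1e-12)

    def test_two_overlaps_agree_on_smooth_input(self, rng):
        from scipy import ndimage
        net = self._net()
        vol = ndimage.gaussian_filter(rng.random((16, 16, 8)), 3.0)
        a = predict_tiled(net, vol, (8, 8, 4), overlap=(2, 2, 2))
        b = predict_tiled(net, vol, (8, 8, 4), overlap=(4, 4, 2))
        assert np.abs(a - b).mean() < 0.1 * np.ptp(a)
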