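"""Network blocks, scope sharing, losses, GAN step and checkpoints."""

import numpy as np
import pytest

from voxpipe.nn import (
    Adam,
    CheckpointError,
    IdentityNet,
    MLP,
    Module,
    ReferenceSegNet,
    SGD,
    Tensor,
    bce_with_logits,
    build_reference_segnet,
    conv_block,
    dense_feature_stack,
    gan_alternating_step,
    restore_checkpoint,
    rmse_loss,
    save_checkpoint,
    soft_dice_loss,
    softmax,
)
from voxpipe.nn import autodiff as ad
from voxpipe.nn.layers import NetworkError, resolve_network


class TestConvBlock:
    def test_identity_kernel_with_linear_activation_passes_input(self, rng):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, 2, 4, 4, 4)).astype(np.float32))
        y = conv_block(net, x, 2, kernel=1, activation="linear",
                       normalize=False, name="c")
        # overwrite with identity weights and re-run: same scope, same params
        net.params["net/c/w"].data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1, 1)
        net.params["net/c/b"].data[:] = 0
        y2 = conv_block(net, x, 2, kernel=1, activation="linear",
                        normalize=False, name="c")
        np.testing.assert_allclose(y2.data, x.data, atol=1e-6)

    def test_same_padding_preserves_spatial_shape(self, rng):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, 3, 5, 6, 7)).astype(np.float32))
        y = conv_block(net, x, 4, kernel=3, name="c")
        assert y.shape == (1, 4, 5, 6, 7)

    def test_scope_reuse_shares_parameters(self, rng):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, 2, 4, 4, 4)).astype(np.float32))
        conv_block(net, x, 3, name="shared")
        n_params = len(net.params)
        conv_block(net, x, 3, name="shared")
        assert len(net.params) == n_params

    def test_scope_reuse_with_wrong_shape_is_an_error(self, rng):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, 2, 4, 4, 4)).astype(np.float32))
        conv_block(net, x, 3, name="shared")
        with pytest.raises(NetworkError, match="shape"):
            conv_block(net, x, 5, name="shared")


class TestDenseFeatureStack:
    def test_single_block_is_plain_conv_block(self, rng):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, 4, 4, 4, 4)).astype(np.float32))
        y = dense_feature_stack(net, x, 1, 8)
        assert y.shape == (1, 8, 4, 4, 4)

    @pytest.mark.parametrize("c0,growth,n_blocks", [
        (4, 8, 3), (1, 2, 4), (3, 5, 2), (2, 2, 1),
    ])
    def test_channel_arithmetic(self, rng, c0, growth, n_blocks):
        net = Module("net", init_rng=rng)
        x = Tensor(rng.random((1, c0, 4, 4, 4)).astype(np.float32))
        y = dense_feature_stack(net, x, n_blocks, growth)
        assert y.shape[1] == n_blocks * growth
        for i in range(n_blocks):
            w = net.params[f"net/dfs/block{i + 1}/w"]
            assert w.data.shape[1] == c0 + i * growth

    def test_gradient_reaches_first_block_from_final_output(self, rng):
        # finite-difference check on a tiny input: dense connectivity means
        # block-1 weights influence the concatenated stack output
        net = Module("net", init_rng=np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, 1, 2, 1, 1)).astype(np.float32)

        def loss():
            y = dense_feature_stack(net, Tensor(x), 3, 2)
            return ad.sum_(ad.mul(y, y))

        l = loss()
        net.zero_grad()
        l.backward()
        w1 = net.params["net/dfs/block1/w"]
        g = w1.grad
        assert g is not None and np.abs(g).max() > 0
        idx = np.unravel_index(np.abs(g).argmax(), g.shape)
        eps = 1e-3
        orig = w1.data[idx]
        w1.data[idx] = orig + eps
        lp = float(loss().data)
        w1.data[idx] = orig - eps
        lm = float(loss().data)
        w1.data[idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - g[idx]) / max(abs(fd), abs(g[idx])) < 0.05


class TestReferenceSegNet:
    def test_output_shape_and_scope_tree(self, rng):
        net = build_reference_segnet(2, 3)
        x = Tensor(rng.random((1, 2, 8, 8, 8)).astype(np.float32))
        y = net.forward(x)
        assert y.shape == (1, 3, 8, 8, 8)
        top = net.handle("segnet").child_layers
        assert "level0" in top and "level1" in top and "classifier" in top

    def test_indivisible_spatial_shape_is_an_error(self, rng):
        net = ReferenceSegNet(1, 2, depth=2)
        with pytest.raises(NetworkError, match="divisible"):
            net.forward(Tensor(np.zeros((1, 1, 6, 6, 6), dtype=np.float32)))

    def test_forward_is_deterministic(self, rng):
        net = ReferenceSegNet(1, 2, init_rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 1, 8, 8, 8)).astype(np.float32))
        y1 = net.forward(x).data
        y2 = net.forward(x).data
        np.testing.assert_array_equal(y1, y2)


class TestLosses:
    def test_perfect_one_hot_prediction_has_near_zero_dice_loss(self, rng):
        labels = rng.integers(0, 3, (1, 4, 4, 4))
        from voxpipe.nn.losses import one_hot
        probs = Tensor(one_hot(labels, 3))
        assert float(soft_dice_loss(probs, labels, 3).data) <= 1e-4

    def test_complement_prediction_has_dice_loss_near_one(self):
        labels = np.zeros((1, 3, 3, 3), dtype=int)
        from voxpipe.nn.losses import one_hot
        probs = Tensor(one_hot(1 - labels, 2))
        assert float(soft_dice_loss(probs, labels, 2).data) > 0.999

    def test_hand_computed_two_voxel_value(self):
        # 2 voxels, 2 classes, p = (0.5, 0.5) each, labels (0, 1)
        probs = Tensor(np.full((1, 2, 2, 1, 1), 0.5, dtype=np.float32))
        labels = np.array([0, 1]).reshape(1, 2, 1, 1)
        eps = 1e-5
        expected = 1.0 - (2 * 0.5 + eps) / (1 + 1 + eps)
        assert abs(float(soft_dice_loss(probs, labels, 2).data) - expected) < 1e-6

    def test_label_out_of_range_is_an_error(self):
        from voxpipe.nn.losses import LossError
        probs = Tensor(np.full((1, 2, 1, 1, 1), 0.5))
        with pytest.raises(LossError, match="outside"):
            soft_dice_loss(probs, np.array([[[[5]]]]), 2)

    def test_rmse_identity_constant_and_hand_value(self):
        p = Tensor(np.array([1.0, 2.0], dtype=np.float32).reshape(1, 1, 2, 1, 1))
        assert float(rmse_loss(p, p.data).data) == 0.0
        assert abs(float(rmse_loss(p, p.data - 3.0).data) - 3.0) < 1e-6
        t = np.array([3.0, 2.0], dtype=np.float32).reshape(1, 1, 2, 1, 1)
        assert abs(float(rmse_loss(p, t).data) - np.sqrt(2.0)) < 1e-6

    def test_soft_dice_of_one_hot_equals_mean_hard_dice(self, rng):
        # cross-module consistency with the evaluation metrics
        from voxpipe.evaluation import confusion_counts, overlap_metrics
        from voxpipe.nn.losses import one_hot
        n_classes = 3
        for _ in range(10):
            seg = rng.integers(0, n_classes, (6, 6, 6))
            ref = rng.integers(0, n_classes, (6, 6, 6))
            probs = Tensor(one_hot(seg[np.newaxis], n_classes))
            soft = 1.0 - float(soft_dice_loss(probs, ref[np.newaxis], n_classes).data)
            hard = np.mean([
                overlap_metrics(confusion_counts(seg, ref, c))["dice"]
                for c in range(n_classes)
            ])
            assert abs(soft - hard) < 1e-4


class TestGAN:
    def _toy(self, seed):
        rng = np.random.default_rng(seed)
        gen = MLP([1, 1], final_activation=None, name="gen",
                  init_rng=np.random.default_rng(seed))
        disc = MLP([1, 1], final_activation=None, name="disc",
                   init_rng=np.random.default_rng(seed + 1))
        gen.build((1, 1))
        disc.build((1, 1))
        return rng, gen, disc

    def test_alternating_step_parameter_partition_is_bitwise(self):
        rng, gen, disc = self._toy(0)
        gen_before = {k: v.data.copy() for k, v in gen.params.items()}
        g_opt, d_opt = SGD(gen.variables(), 0.05), SGD(disc.variables(), 0.05)

        # patch the optimizers to observe each phase separately
        real = rng.normal(4.0, 1.0, (16, 1))
        noise = rng.normal(0.0, 1.0, (16, 1))

        class NoOp:
            def step(self):
                pass

        gan_alternating_step(gen, disc, real, noise, NoOp(), d_opt)
        for k, v in gen.params.items():
            np.testing.assert_array_equal(v.data, gen_before[k])
        disc_after_d = {k: v.data.copy() for k, v in disc.params.items()}
        gan_alternating_step(gen, disc, real, noise, g_opt, NoOp())
        for k, v in disc.params.items():
            np.testing.assert_array_equal(v.data, disc_after_d[k])

    def test_toy_gan_closes_mean_gap(self):
        # generator = affine map of noise, discriminator = logistic
        # regression; 500 alternating steps should halve the mean gap
        passes = 0
        for seed in (0, 1, 2):
            rng, gen, disc = self._toy(seed)
            g_opt = Adam(gen.variables(), lr=0.05)
            d_opt = Adam(disc.variables(), lr=0.05)
            target_mean = 3.0
            gap0 = None
            for step in range(500):
                real = rng.normal(target_mean, 0.5, (32, 1))
                noise = rng.normal(0.0, 1.0, (32, 1))
                gan_alternating_step(gen, disc, real, noise, g_opt, d_opt)
                if step == 0:
                    fake = gen.forward(Tensor(noise.astype(np.float32))).data
                    gap0 = abs(fake.mean() - target_mean)
            noise = rng.normal(0.0, 1.0, (512, 1))
            fake = gen.forward(Tensor(noise.astype(np.float32))).data
            if abs(fake.mean() - target_mean) <= 0.5 * gap0:
                passes += 1
        assert passes >= 2


class TestCheckpoints:
    def test_save_restore_round_trip_is_bitwise(self, tmp_path, rng):
        net = ReferenceSegNet(1, 2, depth=1, init_rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 1, 4, 4, 4)).astype(np.float32))
        y_before = net.forward(x).data.copy()
        save_checkpoint(net, 7, "[system]\n", tmp_path / "ckpt")

        fresh = ReferenceSegNet(1, 2, depth=1, init_rng=np.random.default_rng(99))
        fresh.build((1, 1, 4, 4, 4))
        step = restore_checkpoint(tmp_path / "ckpt", fresh)
        assert step == 7
        np.testing.assert_array_equal(fresh.forward(x).data, y_before)

    def test_scope_renamed_restore_transplants_block(self, tmp_path, rng):
        src = Module("net", init_rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 2, 4, 4, 4)).astype(np.float32))
        y_src = dense_feature_stack(src, x, 2, 4, name="dfs1").data.copy()
        save_checkpoint(src, 0, "", tmp_path / "ckpt")

        dst = Module("net2", init_rng=np.random.default_rng(5))
        dense_feature_stack(dst, x, 2, 4, name="encoder")
        restore_checkpoint(tmp_path / "ckpt", dst,
                           scope_renames={"net/dfs1": "net2/encoder"}, subset=True)
        y_dst = dense_feature_stack(dst, x, 2, 4, name="encoder").data
        np.testing.assert_array_equal(y_dst, y_src)

    def test_restore_with_wrong_shape_is_an_error(self, tmp_path, rng):
        src = Module("net", init_rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 2, 4, 4, 4)).astype(np.float32))
        dense_feature_stack(src, x, 2, 4, name="dfs")
        save_checkpoint(src, 0, "", tmp_path / "ckpt")
        dst = Module("net", init_rng=np.random.default_rng(1))
        dense_feature_stack(dst, x, 2, 8, name="dfs")
        with pytest.raises(CheckpointError, match="shape"):
            restore_checkpoint(tmp_path / "ckpt", dst)

    def test_unmatched_scope_is_an_error(self, tmp_path, rng):
        src = Module("net", init_rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 1, 2, 2, 2)).astype(np.float32))
        conv_block(src, x, 2, name="a")
        save_checkpoint(src, 0, "", tmp_path / "ckpt")
        dst = Module("net", init_rng=np.random.default_rng(1))
        conv_block(dst, x, 2, name="b")
        with pytest.raises(CheckpointError, match="unmatched"):
            restore_checkpoint(tmp_path / "ckpt", dst)


def test_resolve_network_builtin_and_plugin():
    assert resolve_network("identity") is IdentityNet
    cls = resolve_network("voxpipe.nn.layers:ReferenceSegNet")
    assert cls is ReferenceSegNet
    with pytest.raises(NetworkError):
        resolve_network("no_such_thing")
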