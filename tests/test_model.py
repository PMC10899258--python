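"""Architecture contracts: blocks, shortcuts, shapes, parameter counts."""

import numpy as np
import pytest

from slumbernet.model import (
    ModelConfig,
    ResBlockSpec,
    build_block,
    build_model,
    count_trainable_parameters,
    forward,
    load_checkpoint,
    save_checkpoint,
    summarize,
)
from slumbernet.nn import BatchNorm, Conv2D, Dense, ResidualBlock


class TestConfig:
    def test_published_hyperparameter_defaults(self):
        cfg = ModelConfig()
        assert cfg.num_epochs == 50
        assert cfg.learning_rate == 1e-6
        assert cfg.batch_size == 128
        assert cfg.optimizer_name == "Adam"
        assert cfg.n_resnet_blocks == 7
        assert cfg.n_feature_maps == 8
        assert cfg.kernel == (2, 1)
        assert cfg.strides == (1, 1)
        assert cfg.dropout_rate == 0.0
        assert cfg.input_shape == (256, 2, 1)

    def test_block_widths_double(self):
        assert ModelConfig().block_widths == [8, 16, 32, 64, 128, 256, 512]
        assert ModelConfig(n_resnet_blocks=2, n_feature_maps=4).block_widths == [4, 8]

    def test_kernel_orientation_switch(self):
        assert ModelConfig().effective_kernel == (2, 1)
        assert ModelConfig(kernel_orientation="signal").effective_kernel == (1, 2)
        with pytest.raises(ValueError):
            ModelConfig(kernel_orientation="diagonal")


class TestBlock:
    def test_identity_shortcut_when_widths_match(self):
        block = build_block(ResBlockSpec(8, 8))
        assert not block.has_projection

    def test_projection_shortcut_on_width_change(self):
        block = build_block(ResBlockSpec(8, 16))
        assert block.has_projection
        assert isinstance(block.shortcut[0], Conv2D)

    def test_output_extent_matches_input(self, rng):
        block = build_block(ResBlockSpec(4, 8))
        x = rng.standard_normal((3, 32, 2, 4))
        assert block.forward(x).shape == (3, 32, 2, 8)

    def test_residual_identity_with_zeroed_body(self, rng):
        """Zeroing the body's final conv+BN makes the block ReLU(shortcut)."""
        block = build_block(ResBlockSpec(4, 4), rng=np.random.default_rng(0))
        final_conv, final_bn = block.body[-2], block.body[-1]
        final_conv.params[0][:] = 0.0
        final_conv.params[1][:] = 0.0
        final_bn.params[0][:] = 0.0  # gamma = 0 kills the body path exactly
        x = rng.standard_normal((2, 16, 2, 4))
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0.0), atol=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_block(ResBlockSpec(0, 4))


class TestBuildAndForward:
    def test_default_structure(self):
        model = build_model(ModelConfig())
        assert len(model.blocks) == 7
        assert model.blocks[-1].out_maps == 512
        assert model.dense.params[0].shape == (512, 3)

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(ModelConfig(n_resnet_blocks=2, n_feature_maps=4))
        probs = forward(model, rng.standard_normal((5, 256, 2, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_duplicated_inputs_give_identical_rows(self, rng):
        model = build_model(ModelConfig(n_resnet_blocks=1, n_feature_maps=4))
        x = rng.standard_normal((1, 256, 2, 1))
        probs = forward(model, np.concatenate([x, x]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_batch_permutation_equivariance(self, rng):
        model = build_model(ModelConfig(n_resnet_blocks=1, n_feature_maps=4))
        x = rng.standard_normal((6, 256, 2, 1))
        perm = rng.permutation(6)
        np.testing.assert_allclose(forward(model, x)[perm],
                                   forward(model, x[perm]), atol=1e-12)

    def test_fresh_model_near_uniform_average_probabilities(self, rng):
        model = build_model(ModelConfig(n_resnet_blocks=2, n_feature_maps=4, seed=3))
        x = rng.standard_normal((1024, 64, 2, 1))  # shorter epochs, same statistics
        mean_probs = model.forward(x).mean(axis=0)
        assert np.all(np.abs(mean_probs - 1 / 3) < 0.15)

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(ModelConfig(n_resnet_blocks=1, n_feature_maps=4))
        with pytest.raises(ValueError):
            forward(model, rng.standard_normal((4, 256, 2)))


class TestParameterCounts:
    def test_single_conv_closed_form(self):
        conv = Conv2D(1, 8, kernel=(2, 1))
        assert conv.n_trainable == 8 * (2 * 1 * 1) + 8 == 24

    def test_batchnorm_closed_form(self):
        bn = BatchNorm(8)
        assert bn.n_trainable == 16
        assert bn.n_non_trainable == 16

    def test_full_model_matches_hand_summed_count(self):
        """Layer-by-layer closed-form sum must equal the walked total."""
        cfg = ModelConfig()
        model = build_model(cfg)

        def conv_params(cin, cout, kt, ks):
            return kt * ks * cin * cout + cout

        expected = 0
        cin = 1
        for w in cfg.block_widths:
            kt, ks = cfg.effective_kernel
            expected += conv_params(cin, w, kt, ks) + 2 * w   # conv1 + bn
            expected += conv_params(w, w, kt, ks) + 2 * w     # conv2 + bn
            expected += conv_params(w, w, kt, ks) + 2 * w     # conv3 + bn
            if cin != w:
                expected += conv_params(cin, w, 1, 1) + 2 * w  # projection
            cin = w
        expected += 512 * 3 + 3  # dense head
        assert count_trainable_parameters(model) == expected

    def test_summary_lists_every_layer(self):
        model = build_model(ModelConfig(n_resnet_blocks=2, n_feature_maps=4))
        text = summarize(model)
        assert "Conv2D" in text and "total" in text
        assert str(count_trainable_parameters(model)) in text


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, tmp_path, rng):
        cfg = ModelConfig(n_resnet_blocks=2, n_feature_maps=4, seed=1)
        model = build_model(cfg)
        x = rng.standard_normal((3, 256, 2, 1))
        before = forward(model, x)
        save_checkpoint(tmp_path / "ckpt", model, cfg, extra={"seed": 1})
        loaded, cfg2, meta = load_checkpoint(tmp_path / "ckpt")
        assert cfg2 == cfg
        assert meta["seed"] == 1
        np.testing.assert_array_equal(forward(loaded, x), before)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences on a tiny net."""
        cfg = ModelConfig(n_resnet_blocks=2, n_feature_maps=3, seed=1)
        model = build_model(cfg)
        x = rng.standard_normal((4, 16, 2, 1))
        y = np.eye(3)[rng.integers(0, 3, 4)]
        params, grads = model.parameters()
        eps = 1e-5
        checked = 0
        for p, g in zip(params, grads):
            model.loss_and_grads(x, y)
            analytic = g.copy()
            flat = p.ravel()
            for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                l1 = model.loss_and_grads(x, y)
                flat[k] = orig - eps
                l2 = model.loss_and_grads(x, y)
                flat[k] = orig
                numeric = (l1 - l2) / (2 * eps)
                assert analytic.ravel()[k] == pytest.approx(numeric, rel=1e-3, abs=1e-7)
                checked += 1
        assert checked >= 20


class TestResidualBlockInternals:
    def test_body_layer_sequence(self):
        block = ResidualBlock(4, 8)
        names = [type(l).__name__ for l in block.body]
        assert names == ["Conv2D", "BatchNorm", "Dropout", "ReLU"] * 2 + ["Conv2D", "BatchNorm"]

    def test_dense_and_bn_layers_counted_once(self):
        model = build_model(ModelConfig(n_resnet_blocks=2, n_feature_maps=4))
        layers = model.layers()
        assert sum(isinstance(l, Dense) for l in layers) == 1
        # 3 body BNs per block + 1 projection BN per block (both blocks widen)
        assert sum(isinstance(l, BatchNorm) for l in layers) == 8
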