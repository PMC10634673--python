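"""Detector architecture contracts: shapes, padding, invariants."""

import numpy as np
import pytest

from cryopicker.autodiff import Tensor, no_grad
from cryopicker.model import (
    FeatureMap,
    ModelConfig,
    SetPredictionDetector,
    sinusoidal_positions_2d,
    tiny_model_config,
)


@pytest.fixture(scope="module")
def tiny_model():
    model = SetPredictionDetector(tiny_model_config(n_queries=12), seed=0)
    model.eval()
    return model


class TestConfig:
    def test_defaults_follow_full_scale_architecture(self):
        cfg = ModelConfig()
        assert cfg.backbone_depth == "resnet152"
        assert cfg.channels == 2048
        assert cfg.n_queries == 600
        assert cfg.dropout == 0.1

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_dim=65, n_heads=8)


class TestExtractFeatures:
    def test_32x_downsampling(self, tiny_model):
        fmap = tiny_model.extract_features(np.zeros((1, 256, 256)))
        assert fmap.values.shape == (1, 64, 8, 8)

    def test_64px_input_gives_2x2(self, tiny_model):
        fmap = tiny_model.extract_features(np.random.default_rng(0).normal(size=(1, 64, 64)))
        assert fmap.values.shape[2:] == (2, 2)

    def test_batch_padding_masks_padded_cells(self, tiny_model):
        # a 64x64 image inside a 128x128 padded canvas: the cells covering
        # only padding must be masked
        img = np.zeros((1, 128, 128))
        mask = np.ones((1, 128, 128), dtype=bool)
        mask[:, :64, :64] = False
        fmap = tiny_model.extract_features(img, mask)
        assert fmap.mask.shape == (1, 4, 4)
        assert not fmap.mask[0, :2, :2].any()
        assert fmap.mask[0, 2:, :].all() and fmap.mask[0, :, 2:].all()

    def test_too_small_image_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="at least"):
            tiny_model.extract_features(np.zeros((1, 16, 16)))


class TestEncode:
    def test_memory_length_is_hw(self, tiny_model):
        fmap = tiny_model.extract_features(np.zeros((1, 256, 256)))
        memory, pos, mask, grid = tiny_model.encode(fmap)
        assert memory.shape == (1, 64, 64)
        assert pos.shape == (64, 64)
        assert grid.shape == (64, 2)

    def test_zero_encoder_layers_is_projection_only(self):
        model = SetPredictionDetector(
            tiny_model_config(n_queries=4, n_encoder_layers=0), seed=0
        )
        model.eval()
        img = np.random.default_rng(1).normal(size=(1, 64, 64))
        fmap = model.extract_features(img)
        memory, _, _, _ = model.encode(fmap)
        z0 = model.input_proj(fmap.values)
        b, d, h, w = z0.shape
        expected = z0.reshape(b, d, h * w).transpose(0, 2, 1)
        np.testing.assert_allclose(memory.data, expected.data)

    def test_permutation_equivariance_with_positional_encodings(self):
        """Permuting token positions together with their positional
        encodings permutes the encoder output identically."""
        model = SetPredictionDetector(tiny_model_config(n_queries=4), seed=3)
        model.eval()
        rng = np.random.default_rng(0)
        tokens = Tensor(rng.normal(size=(1, 16, 64)))
        pos = sinusoidal_positions_2d(4, 4, 64)
        mask = np.zeros((1, 16), dtype=bool)
        perm = rng.permutation(16)
        with no_grad():
            out = tokens
            for layer in model.encoder_layers:
                out = layer(out, pos, mask)
            out_perm_in = Tensor(tokens.data[:, perm])
            outp = out_perm_in
            for layer in model.encoder_layers:
                outp = layer(outp, pos[perm], mask)
        np.testing.assert_allclose(outp.data, out.data[:, perm], atol=1e-10)


class TestDecodeAndPredict:
    def test_always_n_outputs_with_valid_distributions(self, tiny_model):
        preds = tiny_model.predict(np.random.default_rng(2).normal(size=(2, 96, 96)))
        assert len(preds) == 2
        for p in preds:
            assert p.boxes.shape == (12, 4)
            assert p.class_probs.shape == (12, 2)
            np.testing.assert_allclose(p.class_probs.sum(axis=1), 1.0, atol=1e-6)
            assert (p.boxes >= 0).all() and (p.boxes <= 1).all()

    def test_eval_forward_is_deterministic(self, tiny_model):
        img = np.random.default_rng(4).normal(size=(1, 64, 64))
        a = tiny_model.predict(img)[0]
        b = tiny_model.predict(img)[0]
        np.testing.assert_array_equal(a.boxes, b.boxes)
        np.testing.assert_array_equal(a.class_probs, b.class_probs)

    def test_train_mode_dropout_gives_stochastic_forward(self):
        model = SetPredictionDetector(tiny_model_config(n_queries=6, dropout=0.1), seed=0)
        model.train()
        img = np.random.default_rng(5).normal(size=(1, 64, 64))
        p1, _ = model.forward(img)
        p2, _ = model.forward(img)
        assert not np.allclose(p1.data, p2.data)

    def test_aux_outputs_one_per_decoder_layer(self, tiny_model):
        img = np.random.default_rng(6).normal(size=(1, 64, 64))
        with no_grad():
            per_layer = tiny_model.forward(img, return_aux=True)
        assert len(per_layer) == tiny_model.cfg.n_decoder_layers
        final_probs, final_boxes = tiny_model.forward(img)
        np.testing.assert_allclose(per_layer[-1][0].data, final_probs.data, atol=1e-12)


class TestPositionalEncoding:
    def test_shape_and_range(self):
        pos = sinusoidal_positions_2d(4, 6, 64)
        assert pos.shape == (24, 64)
        assert np.abs(pos).max() <= 1.0

    def test_distinct_positions_get_distinct_codes(self):
        pos = sinusoidal_positions_2d(8, 8, 64)
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1e-3


def test_parameter_count_grows_with_backbone_depth():
    def n_params(depth, channels):
        cfg = tiny_model_config(n_queries=2)
        cfg = ModelConfig(**{**cfg.__dict__, "backbone_depth": depth, "feature_channels": channels})
        model = SetPredictionDetector(cfg, seed=0)
        return sum(p.size for p in model.backbone.parameters())

    tiny = n_params("tiny", 64)
    r50 = n_params("resnet50", 2048)
    r152 = n_params("resnet152", 2048)
    assert tiny < r50 < r152
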