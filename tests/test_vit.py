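"""Transformer core: patching, embedding, attention, parameter counts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hdsemg.nn import Tensor, scaled_dot_product_attention
from hdsemg.vit import (GestureTransformer, ModelConfig, count_parameters,
                        describe_parameters, make_patches, standard_configs,
                        unmake_patches)

# (variant, window, channels) -> published learnable-parameter count
PARAM_TABLE = {
    ("V1", 64, 32): 46_530,
    ("V1", 128, 32): 47_042,
    ("V1", 256, 32): 48_066,
    ("V1", 64, 64): 62_914,
    ("V1", 128, 64): 63_426,
    ("V1", 256, 64): 64_450,
    ("V1", 64, 128): 95_682,
    ("V1", 128, 128): 96_194,
    ("V1", 256, 128): 97_218,
    ("V1", 512, 128): 99_266,
    ("V2", 64, 128): 273_346,
    ("V2", 128, 128): 274_370,
    ("V2", 256, 128): 276_418,
    ("V2", 512, 128): 280_514,
}


class TestMakePatches:
    @pytest.mark.parametrize("window,expected_n", [
        (64, 8), (128, 16), (256, 32), (512, 64)])
    def test_patch_counts_for_128_channels(self, window, expected_n):
        cfg = standard_configs("V1", window=window, channels=128)
        assert cfg.patch == (8, 16)
        assert cfg.n_patches == expected_n

    def test_tiling_is_invertible(self, rng):
        w = rng.normal(size=(64, 8, 8))
        p = make_patches(w, (8, 8))
        np.testing.assert_array_equal(unmake_patches(p, (8, 8), (64, 8, 8)), w)

    @given(st.sampled_from([(2, 1), (4, 2), (8, 4), (16, 8)]),
           st.integers(1, 4), st.integers(1, 2))
    def test_patch_count_equals_tile_enumeration(self, patch, tb, cb):
        h, v = patch
        w, n_ch, n_cv = h * tb, v * cb, 3
        x = np.arange(w * n_ch * n_cv, dtype=float).reshape(w, n_ch, n_cv)
        p = make_patches(x, patch)
        # brute force: count disjoint HxV tiles over the (time, channel) plane
        tiles = sum(1 for _ in range(0, w, h) for _ in range(0, n_ch, v))
        assert p.shape == (tiles, h * v * n_cv)

    def test_non_divisible_shapes_rejected(self):
        with pytest.raises(ValueError):
            make_patches(np.zeros((10, 8, 8)), (8, 8))


class TestEmbedding:
    def test_zero_patches_keep_class_token_row(self):
        cfg = ModelConfig(d=16, n_heads=4, patch=(4, 4), window=8, n_ch=8,
                          n_cv=2, n_classes=3, mlp_hidden=16)
        model = GestureTransformer(cfg, seed=0)
        model.pos_embedding.data[:] = 0.0
        z0 = model.embed(np.zeros((1, cfg.n_patches, cfg.patch_dim))).data
        np.testing.assert_array_equal(z0[0, 1:], 0.0)
        np.testing.assert_array_equal(z0[0, 0], model.class_token.data)

    def test_identity_projection_reproduces_patch(self, rng):
        cfg = ModelConfig(d=32, n_heads=4, patch=(4, 4), window=4, n_ch=4,
                          n_cv=2, n_classes=3, mlp_hidden=16)
        model = GestureTransformer(cfg, seed=0)
        model.patch_proj.weight.data = np.eye(32)
        patches = rng.normal(size=(1, cfg.n_patches, 32))
        z0 = model.embed(patches).data
        np.testing.assert_allclose(
            z0[0, 1], patches[0, 0] + model.pos_embedding.data[1], atol=1e-12)

    def test_embedding_linearity(self, rng):
        cfg = ModelConfig(d=16, n_heads=4, patch=(4, 4), window=8, n_ch=8,
                          n_cv=2, n_classes=3, mlp_hidden=16)
        model = GestureTransformer(cfg, seed=1)
        p = rng.normal(size=(1, cfg.n_patches, cfg.patch_dim))
        base = model.embed(np.zeros_like(p)).data
        lhs = model.embed(3.0 * p).data - base
        rhs = 3.0 * (model.embed(p).data - base)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestAttention:
    def test_single_token_returns_value_row(self, rng):
        q = Tensor(rng.normal(size=(1, 4)))
        k = Tensor(rng.normal(size=(1, 4)))
        v = Tensor(rng.normal(size=(1, 4)))
        np.testing.assert_allclose(
            scaled_dot_product_attention(q, k, v, 4).data, v.data, atol=1e-12)

    def test_identical_keys_average_values(self, rng):
        k = Tensor(np.tile(rng.normal(size=(1, 4)), (3, 1)))
        q = Tensor(rng.normal(size=(3, 4)))
        v = Tensor(rng.normal(size=(3, 4)))
        out = scaled_dot_product_attention(q, k, v, 4).data
        np.testing.assert_allclose(out, np.tile(v.data.mean(0), (3, 1)),
                                   atol=1e-12)

    def test_two_token_case_matches_hand_computation(self):
        q = np.array([[1.0, 0.0], [0.0, 2.0]])
        k = np.array([[1.0, 1.0], [-1.0, 0.5]])
        v = np.array([[0.5, -0.5], [2.0, 1.0]])
        out = scaled_dot_product_attention(Tensor(q), Tensor(k), Tensor(v),
                                           2).data
        # independent arithmetic: softmax(q k^T / sqrt(2)) v
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out, p @ v, atol=1e-14)

    def test_rows_sum_to_one(self, rng):
        q = Tensor(rng.normal(size=(6, 8)) * 5)
        k = Tensor(rng.normal(size=(6, 8)) * 5)
        scores = (q @ k.swapaxes(-1, -2)) * (1 / np.sqrt(8.0))
        from hdsemg.nn import functional as F
        p = F.softmax(scores, axis=-1).data
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(p >= 0)


class TestEncoderLayer:
    def test_zero_weights_give_pure_residual(self, rng):
        cfg = ModelConfig(d=16, n_heads=4, patch=(4, 4), window=8, n_ch=8,
                          n_cv=2, n_classes=3, mlp_hidden=16)
        model = GestureTransformer(cfg, seed=0)
        layer = model.layers[0]
        for _, p in layer.named_parameters():
            p.data[:] = 0.0
        layer.norm1.weight.data[:] = 1.0
        layer.norm2.weight.data[:] = 1.0
        z = rng.normal(size=(2, 5, 16))
        np.testing.assert_allclose(layer(Tensor(z)).data, z, atol=1e-12)

    def test_single_head_equals_manual_computation(self, rng):
        from hdsemg.nn import MultiheadSelfAttention
        msa = MultiheadSelfAttention(8, 1, np.random.default_rng(2))
        z = rng.normal(size=(1, 4, 8))
        out = msa(Tensor(z)).data
        q = z @ msa.wq.weight.data + msa.wq.bias.data
        k = z @ msa.wk.weight.data + msa.wk.bias.data
        v = z @ msa.wv.weight.data + msa.wv.bias.data
        scores = q[0] @ k[0].T / np.sqrt(8.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        att = (e / e.sum(axis=1, keepdims=True)) @ v[0]
        manual = att @ msa.wo.weight.data + msa.wo.bias.data
        np.testing.assert_allclose(out[0], manual, atol=1e-10)

    def test_shape_preserved(self, rng):
        cfg = standard_configs("V1", 64, 64, n_classes=5)
        model = GestureTransformer(cfg, seed=0)
        z = model.encode(rng.normal(size=(3, 64, 8, 8)))
        assert z.shape == (3, cfg.seq_len, cfg.d)


class TestForward:
    def test_head_reads_class_row_only(self, rng):
        cfg = standard_configs("V1", 64, 64, n_classes=5)
        model = GestureTransformer(cfg, seed=0)
        x = rng.normal(size=(2, 64, 8, 8))
        z = model.encode(x)
        logits = model.head(z[:, 0, :]).data
        perturbed = Tensor(z.data.copy())
        perturbed.data[:, 1:, :] += 100.0
        np.testing.assert_array_equal(model.head(perturbed[:, 0, :]).data,
                                      logits)

    def test_identical_windows_identical_logits(self, rng):
        cfg = standard_configs("V1", 64, 64, n_classes=5)
        model = GestureTransformer(cfg, seed=0)
        w = rng.normal(size=(64, 8, 8))
        batch = np.stack([w, w, w])
        logits = model.forward(batch).data
        np.testing.assert_array_equal(logits[0], logits[1])
        np.testing.assert_array_equal(logits[0], logits[2])

    def test_argmax_tie_breaks_to_lowest_index(self):
        assert np.argmax(np.array([1.0, 1.0, 0.5])) == 0

    def test_forward_deterministic(self, rng):
        cfg = standard_configs("V1", 64, 64, n_classes=5)
        x = rng.normal(size=(2, 64, 8, 8))
        a = GestureTransformer(cfg, seed=9).forward(x).data
        b = GestureTransformer(cfg, seed=9).forward(x).data
        np.testing.assert_array_equal(a, b)


class TestParameterCounts:
    @pytest.mark.parametrize("key", sorted(PARAM_TABLE), ids=str)
    def test_closed_form_matches_published_table(self, key):
        name, window, channels = key
        cfg = standard_configs(name, window=window, channels=channels)
        assert count_parameters(cfg) == PARAM_TABLE[key]

    @pytest.mark.parametrize("key", sorted(PARAM_TABLE), ids=str)
    def test_closed_form_matches_model_introspection(self, key):
        name, window, channels = key
        cfg = standard_configs(name, window=window, channels=channels)
        model = GestureTransformer(cfg, seed=0)
        assert model.n_parameters() == count_parameters(cfg)

    def test_breakdown_sums_to_total(self):
        cfg = standard_configs("V1", 64, 32)
        parts = describe_parameters(cfg)
        assert parts["total"] == count_parameters(cfg)
        assert parts["total"] == sum(v for k, v in parts.items()
                                     if k != "total")

    def test_introspection_for_special_variants(self):
        for name in ("V3", "instantaneous"):
            cfg = standard_configs(name, n_classes=10)
            model = GestureTransformer(cfg, seed=0)
            assert model.n_parameters() == count_parameters(cfg)


class TestStandardConfigs:
    def test_v3_yields_two_patches(self):
        assert standard_configs("V3").n_patches == 2

    def test_instantaneous_sequence_length_two(self):
        cfg = standard_configs("instantaneous")
        assert cfg.n_patches == 1
        assert cfg.seq_len == 2

    def test_v1_patch_scales_with_channels(self):
        assert standard_configs("V1", channels=32).patch == (8, 4)
        assert standard_configs("V1", channels=64).patch == (8, 8)
        assert standard_configs("V1", channels=128).patch == (8, 16)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            standard_configs("V9")


class TestPermutationSensitivity:
    def test_positions_make_patch_order_matter(self, rng):
        cfg = standard_configs("V1", 64, 64, n_classes=5)
        model = GestureTransformer(cfg, seed=4)
        patches = make_patches(rng.normal(size=(64, 8, 8)), cfg.patch)
        perm = np.random.default_rng(0).permutation(cfg.n_patches)

        def logits(p):
            z = model.embed(p[None])
            for layer in model.layers:
                z = layer(z)
            return model.head(z[:, 0, :]).data

        assert not np.allclose(logits(patches), logits(patches[perm]))
        # with zero positional embedding the encoder is permutation invariant
        model.pos_embedding.data[:] = 0.0
        np.testing.assert_allclose(logits(patches), logits(patches[perm]),
                                   atol=1e-8)
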