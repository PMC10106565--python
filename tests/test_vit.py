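"""Transformer bottleneck: patch embedding, attention, MSA, layers."""

import numpy as np
import pytest

import oracles
from glsegnet.autograd import Tensor
from glsegnet.config import ViTConfig
from glsegnet.exceptions import ConfigurationError
from glsegnet.vit import (MultiHeadSelfAttention, PatchEmbed, TransformerLayer,
                          ViTBottleneck, attention)


def _zero_params(module):
    for _, p in module.named_parameters():
        p.data = np.zeros_like(p.data)


class TestPatchEmbed:
    def test_token_counts(self):
        pe = PatchEmbed(4, 1, 8, (16, 16), rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(0).random((2, 4, 16, 16)))
        assert pe(x).shape == (2, 256, 8)
        pe2 = PatchEmbed(4, 16, 8, (1, 1), rng=np.random.default_rng(0))
        assert pe2(x).shape == (2, 1, 8)

    def test_indivisible_patch_raises(self):
        pe = PatchEmbed(1, 3, 4, (2, 2), rng=np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            pe(Tensor(np.zeros((1, 1, 8, 8))))

    def test_identity_embedding_returns_raw_patches(self):
        # B = identity, B_pos = 0, one channel: tokens are the flat patches
        P, C = 2, 1
        pe = PatchEmbed(C, P, P * P * C, (2, 2), rng=np.random.default_rng(0))
        pe.proj.weight.data = np.eye(P * P * C)
        pe.proj.bias.data = np.zeros(P * P * C)
        pe.pos.data = np.zeros_like(pe.pos.data)
        x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
        tokens = pe(Tensor(x)).data[0]
        # manual patch slicing oracle, row-major over the patch grid
        expected = []
        for gi in range(2):
            for gj in range(2):
                patch = x[0, :, gi * P:(gi + 1) * P, gj * P:(gj + 1) * P]
                expected.append(patch.transpose(1, 2, 0).ravel())
        np.testing.assert_allclose(tokens, np.array(expected))


class TestAttention:
    def test_single_token_returns_value(self, rng):
        q = rng.standard_normal((1, 4))
        v = rng.standard_normal((1, 6))
        out = attention(Tensor(q), Tensor(q), Tensor(v))
        np.testing.assert_allclose(out.data, v, rtol=1e-12)

    def test_orthogonal_query_gives_value_mean(self, rng):
        k = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        q = np.zeros((2, 2))          # QK^T = 0 -> uniform softmax
        v = rng.standard_normal((3, 5))
        out = attention(Tensor(q), Tensor(k), Tensor(v))
        np.testing.assert_allclose(out.data, np.tile(v.mean(axis=0), (2, 1)),
                                    rtol=1e-10, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            q = rng.standard_normal((3, 4))
            k = rng.standard_normal((3, 4))
            v = rng.standard_normal((3, 4))
            out = attention(Tensor(q), Tensor(k), Tensor(v))
            np.testing.assert_allclose(out.data, oracles.attention_loop(q, k, v),
                                       rtol=1e-8, atol=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ConfigurationError):
            attention(Tensor(rng.random((2, 3))), Tensor(rng.random((2, 4))),
                      Tensor(rng.random((2, 4))))

    def test_softmax_rows_sum_to_one(self, rng):
        from glsegnet import autograd as ag
        for _ in range(20):
            s = ag.softmax(Tensor(rng.standard_normal((5, 7)) * 10))
            np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)


class TestMSA:
    def test_single_head_reduces_to_attention(self, rng):
        msa = MultiHeadSelfAttention(6, 1, rng=np.random.default_rng(2),
                                     dtype=np.float64)
        msa.wo.weight.data = np.eye(6)
        msa.wo.bias.data = np.zeros(6)
        x = rng.standard_normal((1, 4, 6))
        q = x[0] @ msa.wq.weight.data + msa.wq.bias.data
        k = x[0] @ msa.wk.weight.data + msa.wk.bias.data
        v = x[0] @ msa.wv.weight.data + msa.wv.bias.data
        expected = attention(Tensor(q), Tensor(k), Tensor(v)).data
        np.testing.assert_allclose(msa(Tensor(x)).data[0], expected, rtol=1e-10)

    def test_zero_value_projection_gives_zero(self, rng):
        msa = MultiHeadSelfAttention(8, 2, rng=np.random.default_rng(0))
        msa.wv.weight.data = np.zeros_like(msa.wv.weight.data)
        msa.wv.bias.data = np.zeros_like(msa.wv.bias.data)
        msa.wo.bias.data = np.zeros_like(msa.wo.bias.data)
        out = msa(Tensor(rng.standard_normal((2, 5, 8))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_per_head_oracle(self, rng):
        msa = MultiHeadSelfAttention(8, 2, rng=np.random.default_rng(7),
                                     dtype=np.float64)
        for _ in range(10):
            x = rng.standard_normal((4, 8))
            expected = oracles.msa_loop(
                x, msa.wq.weight.data, msa.wk.weight.data, msa.wv.weight.data,
                msa.wo.weight.data, msa.wq.bias.data, msa.wk.bias.data,
                msa.wv.bias.data, msa.wo.bias.data, n_heads=2)
            got = msa(Tensor(x[None])).data[0]
            np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_indivisible_heads_raise(self):
        with pytest.raises(ConfigurationError):
            MultiHeadSelfAttention(7, 2, rng=np.random.default_rng(0))


class TestTransformerLayer:
    def test_zero_sublayers_is_identity(self, rng):
        layer = TransformerLayer(8, 16, 2, rng=np.random.default_rng(0))
        for name, p in layer.named_parameters():
            if name.startswith(("msa", "mlp")):
                p.data = np.zeros_like(p.data)
        x = rng.standard_normal((2, 5, 8))
        np.testing.assert_allclose(layer(Tensor(x)).data, x, atol=1e-12)

    def test_mlp_relu_clips_negatives(self):
        from glsegnet.vit import MLP
        mlp = MLP(2, 2, rng=np.random.default_rng(0), dtype=np.float64)
        mlp.fc1.weight.data = np.eye(2)
        mlp.fc1.bias.data = np.zeros(2)
        mlp.fc2.weight.data = np.eye(2)
        mlp.fc2.bias.data = np.zeros(2)
        out = mlp(Tensor(np.array([[-1.0, 1.0]])))
        np.testing.assert_allclose(out.data, [[0.0, 1.0]])

    def test_matches_manual_composition(self, rng):
        layer = TransformerLayer(8, 16, 2, rng=np.random.default_rng(11),
                                 dtype=np.float64)
        x = rng.standard_normal((3, 8))
        ln1 = oracles.layer_norm_loop(x, layer.ln1.gamma.data, layer.ln1.beta.data)
        m = layer.msa
        msa_out = oracles.msa_loop(
            ln1, m.wq.weight.data, m.wk.weight.data, m.wv.weight.data,
            m.wo.weight.data, m.wq.bias.data, m.wk.bias.data, m.wv.bias.data,
            m.wo.bias.data, n_heads=2)
        mid = msa_out + x
        ln2 = oracles.layer_norm_loop(mid, layer.ln2.gamma.data, layer.ln2.beta.data)
        mlp_out = oracles.mlp_loop(ln2, layer.mlp.fc1.weight.data,
                                   layer.mlp.fc1.bias.data,
                                   layer.mlp.fc2.weight.data,
                                   layer.mlp.fc2.bias.data)
        expected = mlp_out + mid
        got = layer(Tensor(x[None])).data[0]
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)


class TestViTBottleneck:
    def test_shape_bookkeeping_base_config(self, rng):
        cfg = ViTConfig.preset("base")
        vit = ViTBottleneck(512, cfg, ref_size=16, rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 512, 16, 16), dtype=np.float32))
        tokens = vit.embed(x)
        assert tokens.shape == (1, 256, 768)
        out = vit(x)
        assert out.shape == (1, 512, 16, 16)

    def test_presets_match_published_sizes(self):
        base = ViTConfig.preset("base")
        large = ViTConfig.preset("large")
        assert (base.n_layers, base.hidden_dim, base.mlp_dim) == (12, 768, 3072)
        assert (large.n_layers, large.hidden_dim, large.mlp_dim) == (24, 1024, 4096)

    def test_zero_layers_pass_embedding_through(self, rng):
        cfg = ViTConfig(n_layers=2, hidden_dim=8, mlp_dim=16, n_heads=2)
        vit = ViTBottleneck(4, cfg, ref_size=4, rng=np.random.default_rng(0),
                            dtype=np.float64)
        for layer in vit.layers:
            for name, p in layer.named_parameters():
                if name.startswith(("msa", "mlp")):
                    p.data = np.zeros_like(p.data)
        x = Tensor(rng.standard_normal((1, 4, 4, 4)))
        tokens = vit.embed(x)
        expected = vit.norm(tokens)
        grid = expected.reshape(1, 4, 4, 8).transpose(0, 3, 1, 2)
        expected_out = vit.out_proj(grid).data
        np.testing.assert_allclose(vit(x).data, expected_out, atol=1e-12)

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = ViTConfig(n_layers=1, hidden_dim=8, mlp_dim=16, n_heads=2)
        vit = ViTBottleneck(4, cfg, ref_size=4, rng=np.random.default_rng(3),
                            dtype=np.float64)
        vit.embed.pos.data = np.zeros_like(vit.embed.pos.data)
        x = rng.standard_normal((1, 4, 4, 4))
        base = vit(Tensor(x)).data.reshape(4, 16)
        perm = rng.permutation(16)
        xp = x.reshape(1, 4, 16)[:, :, perm].reshape(1, 4, 4, 4)
        out = vit(Tensor(xp)).data.reshape(4, 16)
        unshuffled = np.empty_like(out)
        unshuffled[:, perm] = out
        np.testing.assert_allclose(unshuffled, base, rtol=1e-8, atol=1e-10)
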