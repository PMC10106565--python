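"""Context-rich encoder: atrous convolution, residual blocks, MSC/MSP,
multi-scale fusion and the full encoder shape contract."""

import numpy as np
import pytest

import oracles
from glsegnet import autograd as ag
from glsegnet.autograd import Tensor
from glsegnet.config import ModelConfig
from glsegnet.encoder import (AtrousConvSpec, ContextRichEncoder, MSCModule,
                              MSPModule, ResidualBlock, atrous_conv)
from glsegnet.exceptions import ConfigurationError


def _zero_params(module):
    for _, p in module.named_parameters():
        p.data = np.zeros_like(p.data)


class TestAtrousConv:
    def test_rate_one_equals_plain_convolution(self):
        # 1-D case [1,2,3,4,5] * [1,0,1], d=1, pad 1 embedded as a 1xW image
        x = np.array([[[[1., 2., 3., 4., 5.]]]])
        w = np.array([[[[1., 0., 1.]]]])
        spec = AtrousConvSpec((1, 3), 1, 1, 1, padding=(0, 1))
        out = atrous_conv(x, spec, w)
        np.testing.assert_allclose(out.data[0, 0, 0], [2., 4., 6., 8., 4.])

    def test_dilated_1d_matches_loop_oracle(self):
        x = np.array([[[[1., 2., 3., 4., 5.]]]])
        w = np.array([[[[1., 0., 1.]]]])
        out = atrous_conv(x, AtrousConvSpec((1, 3), 2, 1, 1, padding=(0, 2)), w)
        # direct summation of y[i] = sum_l x[i + 2l] w[l] over the padded row
        xp = np.concatenate([[0, 0], x.ravel(), [0, 0]])
        expected = [xp[i] + xp[i + 4] for i in range(5)]
        np.testing.assert_allclose(out.data.ravel(), expected)

    def test_dirac_kernel_is_identity(self, rng):
        x = rng.random((2, 3, 6, 6))
        w = np.zeros((3, 3, 3, 3))
        for c in range(3):
            w[c, c, 1, 1] = 1.0
        for d in (1, 2):
            out = atrous_conv(x, AtrousConvSpec(3, d, 3, 3, padding=d), w)
            np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_matches_dense_oracle_random(self, rng):
        for _ in range(20):
            x = rng.standard_normal((1, 2, 6, 6))
            w = rng.standard_normal((3, 2, 3, 3))
            got = atrous_conv(x, AtrousConvSpec(3, 1, 2, 3, padding=1), w)
            np.testing.assert_allclose(got.data, oracles.conv2d_loop(x, w, padding=1),
                                       rtol=1e-6, atol=1e-9)

    def test_channel_mismatch_raises(self, rng):
        x = rng.random((1, 2, 4, 4))
        with pytest.raises(ConfigurationError):
            atrous_conv(x, AtrousConvSpec(3, 1, 3, 1, padding=1),
                        np.zeros((1, 3, 3, 3)))

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ConfigurationError):
            AtrousConvSpec(3, 0, 1, 1)


class TestResidualBlock:
    def test_zero_residual_branch_is_identity(self, rng):
        blk = ResidualBlock(4, 4, rng=np.random.default_rng(0), dtype=np.float64)
        _zero_params(blk)
        # restore BN scale so the zeroed branch stays zero but adds nothing
        x = Tensor(rng.standard_normal((2, 4, 8, 8)))
        out = blk(x)
        np.testing.assert_allclose(out.data, np.maximum(x.data, 0), atol=1e-12)

    def test_zero_input_equals_manual_composition(self, rng):
        blk = ResidualBlock(3, 3, rng=np.random.default_rng(3), dtype=np.float64)
        blk.conv1.bias.data = rng.standard_normal(3)
        blk.conv2.bias.data = rng.standard_normal(3)
        blk.eval()
        x = np.zeros((1, 3, 6, 6))
        s = 1.0 / np.sqrt(1.0 + blk.bn1.eps)   # fresh BN in eval mode
        h = oracles.conv2d_loop(x, blk.conv1.weight.data, blk.conv1.bias.data,
                                padding=1) * s
        h = np.maximum(h, 0)
        h = oracles.conv2d_loop(h, blk.conv2.weight.data, blk.conv2.bias.data,
                                padding=1) * s
        np.testing.assert_allclose(blk(Tensor(x)).data, np.maximum(h + x, 0),
                                    rtol=1e-8, atol=1e-10)

    def test_transition_block_halves_size_and_doubles_channels(self, rng):
        blk = ResidualBlock(64, 128, stride=2, rng=np.random.default_rng(0))
        out = blk(Tensor(rng.random((1, 64, 128, 128), dtype=np.float32)))
        assert out.shape == (1, 128, 64, 64)


class TestMSC:
    def test_output_shape_equals_input_shape(self, rng):
        for c, h, w in [(8, 32, 32), (4, 48, 64), (64, 128, 128)]:
            msc = MSCModule(c, rng=np.random.default_rng(0))
            out = msc(Tensor(rng.random((1, c, h, w), dtype=np.float32)))
            assert out.shape == (1, c, h, w)

    def test_zero_weights_give_zero_output(self, rng):
        msc = MSCModule(4, rng=np.random.default_rng(0))
        _zero_params(msc)
        out = msc(Tensor(rng.random((1, 4, 32, 32))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_concatenation_has_four_times_channels(self, rng):
        msc = MSCModule(6, rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 6, 32, 32), dtype=np.float32))
        branches = ag.concat([b(x) for b in msc.branches], axis=1)
        assert branches.shape[1] == 4 * 6
        assert msc.fuse.conv.in_channels == 4 * 6

    def test_too_small_input_raises(self, rng):
        msc = MSCModule(2, rng=np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            msc(Tensor(rng.random((1, 2, 8, 8))))


class TestMSP:
    def test_output_is_four_channels_same_size(self, rng):
        msp = MSPModule(8, rng=np.random.default_rng(0))
        out = msp(Tensor(rng.random((2, 8, 32, 32), dtype=np.float32)))
        assert out.shape == (2, 4, 32, 32)

    def test_constant_input_propagates_affine_constant(self):
        msp = MSPModule(2, rng=np.random.default_rng(5), dtype=np.float64)
        c = 0.7
        x = Tensor(np.full((1, 2, 32, 32), c))
        out = msp(x).data
        for k, conv in enumerate(msp.convs):
            expected = float(conv.weight.data.sum() * c + conv.bias.data[0])
            np.testing.assert_allclose(out[0, k], expected, rtol=1e-10)

    def test_spike_matches_pool_then_resize_oracle(self):
        msp = MSPModule(1, rng=np.random.default_rng(1), dtype=np.float64)
        for conv in msp.convs:   # identity 1x1 conv
            conv.weight.data = np.ones_like(conv.weight.data)
            conv.bias.data = np.zeros_like(conv.bias.data)
        x = np.zeros((1, 1, 32, 32))
        x[0, 0, 9, 21] = 1.0
        out = msp(Tensor(x)).data
        for k, size in enumerate(msp.sizes):
            pooled = oracles.maxpool_loop(x[0, 0], size)
            expected = oracles.bilinear_resize_loop(pooled, 32, 32)
            np.testing.assert_allclose(out[0, k], expected, atol=1e-12)

    def test_indivisible_size_raises(self, rng):
        msp = MSPModule(1, rng=np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            msp(Tensor(rng.random((1, 1, 24, 24))))


class TestEncoderForward:
    @pytest.mark.parametrize("size", [64, 128, 256])
    def test_shape_contract(self, size, rng):
        cfg = ModelConfig.tiny(image_size=size)
        enc = ContextRichEncoder(cfg, rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 3, size, size), dtype=np.float32))
        f4, skips = enc(x)
        c = cfg.stem_channels
        assert f4.values.shape == (1, 8 * c, size // 16, size // 16)
        assert f4.scale == 16
        s1, s2, s3 = enc.skip_channels
        assert skips[0].values.shape == (1, s1, size // 2, size // 2)
        assert skips[1].values.shape == (1, s2, size // 4, size // 4)
        assert skips[2].values.shape == (1, s3, size // 8, size // 8)

    def test_level1_skip_channel_arithmetic(self):
        # full-width model: layer-1 (64) + MSC (64) + MSP (4) = 132
        cfg = ModelConfig()
        enc = ContextRichEncoder(cfg, rng=np.random.default_rng(0))
        assert enc.skip_channels[0] == 64 + 64 + 4 == 132
        fb = cfg.fusion_branch_width
        assert enc.skip_channels[1] == 128 + fb
        assert enc.skip_channels[2] == 256 + 2 * fb

    def test_forward_is_deterministic(self, rng):
        enc = ContextRichEncoder(ModelConfig.tiny(),
                                 rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        f4a, skips_a = enc(x)
        f4b, skips_b = enc(x)
        np.testing.assert_array_equal(f4a.values.data, f4b.values.data)
        for a, b in zip(skips_a, skips_b):
            np.testing.assert_array_equal(a.values.data, b.values.data)

    def test_zero_fusion_weights_pad_skips_with_zero_channels(self, rng):
        cfg = ModelConfig.tiny()
        enc = ContextRichEncoder(cfg, rng=np.random.default_rng(0))
        for branch in (enc.l1_to4, enc.l1_to8, enc.l2_to8):
            _zero_params(branch)
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        _, skips = enc(x)
        c2 = cfg.encoder_channels[1]
        np.testing.assert_allclose(skips[1].values.data[:, c2:], 0.0)
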