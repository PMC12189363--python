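"""Architectural contracts: attention normalization, shapes, parameters."""

import numpy as np
import pytest

from cardioseg.errors import ConfigError, StructuralError
from cardioseg.network import (CSEBlock, NetworkConfig, SCSEBlock,
                               SegmentationNet, SplitAttentionConv2d,
                               build_encoder, build_model, count_parameters)
from cardioseg.nn import set_seed
from cardioseg.nn import tensor as T
from cardioseg.nn.tensor import Tensor


class TestSplitAttention:
    def test_radix_weights_sum_to_one(self, rng):
        set_seed(0)
        blk = SplitAttentionConv2d(8, 8, radix=2).eval()
        blk(Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32)))
        att = blk.last_attention            # (n, radix, ch)
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_splits_get_equal_weights(self):
        set_seed(0)
        blk = SplitAttentionConv2d(4, 4, radix=2).eval()
        # surgery: make the expansion conv produce identical radix splits
        w = blk.conv.weight.data
        w[4:] = w[:4]
        blk.bn0.weight.data[4:] = blk.bn0.weight.data[:4]
        blk.bn0.bias.data[4:] = blk.bn0.bias.data[:4]
        blk.bn0.running_mean[4:] = blk.bn0.running_mean[:4]
        blk.bn0.running_var[4:] = blk.bn0.running_var[:4]
        blk.fc2.weight.data[4:] = blk.fc2.weight.data[:4]
        blk.fc2.bias.data[4:] = blk.fc2.bias.data[:4]
        blk(Tensor(np.random.default_rng(0).standard_normal(
            (1, 4, 5, 5)).astype(np.float32)))
        np.testing.assert_allclose(blk.last_attention, 0.5, atol=1e-6)

    def test_radix_one_uses_sigmoid_gate(self, rng):
        set_seed(0)
        blk = SplitAttentionConv2d(4, 4, radix=1).eval()
        blk(Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32)))
        att = blk.last_attention
        assert ((att > 0) & (att < 1)).all()

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigError):
            SplitAttentionConv2d(6, 6, radix=4)


class TestCSE:
    def test_zero_input_zero_output(self):
        set_seed(0)
        blk = CSEBlock(8)
        out = blk(Tensor(np.zeros((1, 8, 4, 4), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_gate_bounds_output_elementwise(self, rng):
        set_seed(0)
        blk = CSEBlock(16)
        x = rng.standard_normal((2, 16, 5, 5)).astype(np.float32)
        out = blk(Tensor(x))
        assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()

    def test_hand_computed_forward(self):
        blk = CSEBlock(2, reduction=2)
        blk.fc1.weight.data[...] = np.array([[[[1.0]], [[0.5]]]],
                                            np.float32)   # (1,2,1,1)
        blk.fc1.bias.data[...] = 0.1
        blk.fc2.weight.data[...] = np.array([[[[2.0]]], [[[-1.0]]]],
                                            np.float32)   # (2,1,1,1)
        blk.fc2.bias.data[...] = np.array([0.0, 0.3], np.float32)
        u = np.array([[[[1.0]], [[3.0]]]], np.float32)    # C=2, H=W=1
        pooled = np.array([1.0, 3.0])
        z = max(pooled @ [1.0, 0.5] + 0.1, 0.0)           # fc1 + relu
        s = 1 / (1 + np.exp(-(np.array([2.0, -1.0]) * z
                              + np.array([0.0, 0.3]))))   # fc2 + sigmoid
        out = blk(Tensor(u))
        np.testing.assert_allclose(out.data[0, :, 0, 0],
                                   pooled * s, rtol=1e-5)

    def test_unit_gate_recovers_identity(self, rng):
        set_seed(0)
        blk = CSEBlock(4)
        # drive the sigmoid to ~1 via a huge positive bias
        blk.fc2.weight.data[...] = 0.0
        blk.fc2.bias.data[...] = 50.0
        x = rng.standard_normal((1, 4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(blk(Tensor(x)).data, x, rtol=1e-5)

    def test_scse_combines_by_maximum(self, rng):
        set_seed(0)
        blk = SCSEBlock(8)
        x = Tensor(np.abs(rng.standard_normal((1, 8, 4, 4))
                          ).astype(np.float32))
        out = blk(x)
        xc = blk.cse(x)
        xs = T.mul(x, T.sigmoid(blk.spatial(x)))
        np.testing.assert_array_equal(out.data,
                                      np.maximum(xc.data, xs.data))


class TestEncoders:
    @pytest.mark.parametrize("variant,chans", [
        ("resnet-34", (3, 64, 64, 128, 256, 512)),
        ("plain", (3, 8, 16, 32, 64, 128)),
    ])
    def test_stage_channels_and_strides(self, variant, chans, rng):
        set_seed(0)
        enc = build_encoder(NetworkConfig(encoder_variant=variant,
                                          plain_width=8)).eval()
        assert enc.out_channels == chans
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with T.no_grad():
            feats = enc(x)
        sizes = [f.shape[2] for f in feats]
        assert sizes == [64, 32, 16, 8, 4, 2]
        assert [f.shape[1] for f in feats] == list(chans)

    def test_split_attention_encoder_channel_plan(self):
        set_seed(0)
        enc = build_encoder(NetworkConfig())
        assert enc.out_channels == (3, 64, 256, 512, 1024, 2048)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(encoder_variant="vgg")


class TestSegmentationNet:
    def test_output_shape_matches_input(self, tiny_model, rng):
        tiny_model.eval()
        with T.no_grad():
            out = tiny_model.forward(
                rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
        assert out.shape == (2, 3, 64, 64)

    def test_softmax_normalization(self, tiny_model, rng):
        p = tiny_model.predict_proba(
            rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_independence_in_eval(self, tiny_model, rng):
        tiny_model.eval()
        a = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        batch = np.concatenate([a, a], axis=0)
        with T.no_grad():
            single = tiny_model.forward(a).data
            double = tiny_model.forward(batch).data
        np.testing.assert_array_equal(double[0], double[1])
        np.testing.assert_allclose(double[0], single[0], atol=1e-5)

    def test_eval_forward_is_deterministic(self, tiny_model, rng):
        tiny_model.eval()
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        with T.no_grad():
            a = tiny_model.forward(x).data
            b = tiny_model.forward(x).data
        assert np.array_equal(a, b)

    def test_indivisible_spatial_size_rejected(self, tiny_model):
        with pytest.raises(StructuralError):
            tiny_model.forward(np.zeros((1, 3, 60, 64), np.float32))

    def test_decoder_grid_node_count(self, tiny_model):
        assert tiny_model.decoder.xgrid_node_count() == 15
        assert len(tiny_model.decoder.blocks) == 11  # 10 grid + final

    def test_plain_unetpp_baseline_has_no_attention_params(self):
        set_seed(0)
        base = SegmentationNet(NetworkConfig(
            encoder_variant="plain", plain_width=8,
            decoder_channels=(32, 16, 8, 8, 8), decoder_attention="none"))
        names = [n for n, _ in base.named_parameters()]
        assert not any("attention" in n for n in names)

    def test_gradient_reaches_every_parameter(self, rng):
        from cardioseg.losses import multiclass_dice_loss, one_hot
        # reduction 4 keeps the attention bottlenecks wide enough that no
        # ReLU unit is dead for every probe batch
        set_seed(0)
        tiny_model = SegmentationNet(NetworkConfig(
            encoder_variant="plain", plain_width=8,
            decoder_channels=(32, 16, 8, 8, 8), cse_reduction=4))
        tiny_model.train()
        for seed in (0, 1):
            r = np.random.default_rng(seed)
            x = r.standard_normal((2, 3, 64, 64)).astype(np.float32)
            g = one_hot(r.integers(0, 3, (2, 64, 64)), 3)
            p = T.softmax(tiny_model.forward(x), axis=1)
            multiclass_dice_loss(p, g).backward()
        for name, param in tiny_model.named_parameters():
            assert param.grad is not None, name
            assert np.abs(param.grad).max() > 0, name
        tiny_model.zero_grad()


class TestParameterCounts:
    def test_head_parameter_arithmetic(self, tiny_cfg):
        set_seed(0)
        model = SegmentationNet(tiny_cfg)
        head = model.head
        c_last = tiny_cfg.decoder_channels[-1]
        assert sum(p.data.size for p in head.parameters()) \
            == c_last * 3 * 9 + 3

    def test_cse_overhead_matches_bottleneck_sum(self):
        """The attention gates add a small parameter overhead that equals
        the closed-form sum of their two-conv bottlenecks."""
        set_seed(0)
        kw = dict(encoder_variant="plain", plain_width=8,
                  decoder_channels=(32, 16, 8, 8, 8))
        none = SegmentationNet(NetworkConfig(decoder_attention="none", **kw))
        cse_model = SegmentationNet(NetworkConfig(decoder_attention="cse",
                                                  **kw))
        n_none = count_parameters(none)
        n_cse = count_parameters(cse_model)
        expected = 0
        for blk in cse_model.decoder.blocks.values():
            for att in (blk.attention1, blk.attention2):
                ch = att.fc2.weight.data.shape[0]
                mid = att.fc1.weight.data.shape[0]
                expected += ch * mid + mid + mid * ch + ch
        assert n_cse - n_none == expected
        assert 0 < n_cse - n_none < 0.05 * n_cse

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            NetworkConfig(decoder_channels=(64, 32, 16))
        with pytest.raises(ConfigError):
            NetworkConfig(n_classes=1)
        with pytest.raises(ConfigError):
            NetworkConfig(decoder_attention="cbam")

    def test_pretrained_weights_unavailable(self):
        with pytest.raises(ConfigError):
            SegmentationNet(NetworkConfig(pretrained=True))
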