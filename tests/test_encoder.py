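"""Hybrid single-modal encoder: shapes, attention oracle, residual
contracts, and parameter independence."""

import numpy as np
import pytest

from thyfuse import nn
from thyfuse.config import EncoderConfig
from thyfuse.encoder import (HybridSingleModalEncoder, ResidualBackbone,
                             SelfAttention, TokenSequence, TransformerBlock,
                             embed_tokens, encode_modality, extract_local_features,
                             intra_self_attention, intra_transformer_block)
from thyfuse.errors import ConfigError, ContractError, NumericError
from thyfuse.nn import Tensor

from conftest import micro_config


def loop_self_attention(x, attn):
    """Independent O(L^2 D) oracle for single-head self-attention,
    including the module's pre-normalization, written as explicit loops."""
    out = np.zeros_like(x)
    w = attn.norm.weight.data
    b = attn.norm.bias.data
    for bi in range(x.shape[0]):
        h = np.empty_like(x[bi])
        for i in range(x.shape[1]):
            row = x[bi, i]
            mu, var = row.mean(), row.var()
            h[i] = (row - mu) / np.sqrt(var + attn.norm.eps) * w + b
        q = h @ attn.query_proj.weight.data + attn.query_proj.bias.data
        k = h @ attn.key_proj.weight.data + attn.key_proj.bias.data
        v = h @ attn.value_proj.weight.data + attn.value_proj.bias.data
        d = x.shape[2]
        for i in range(x.shape[1]):
            scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(x.shape[1])])
            scores -= scores.max()
            weights = np.exp(scores) / np.exp(scores).sum()
            out[bi, i] = sum(weights[j] * v[j] for j in range(x.shape[1]))
    return out


def zero_linears(module):
    for m in module.modules():
        if isinstance(m, nn.Linear):
            m.weight.data[...] = 0.0
            if m.bias is not None:
                m.bias.data[...] = 0.0


class TestBackbone:
    def test_default_backbone_maps_224_input_to_512x7x7(self):
        bb = ResidualBackbone(EncoderConfig(), np.random.default_rng(0)).eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 224, 224)))
        with nn.no_grad():
            f = bb(x)
        assert f.shape == (1, 512, 7, 7)

    def test_zero_input_produces_zero_feature_map(self):
        bb = ResidualBackbone(micro_config().encoder, np.random.default_rng(0)).eval()
        with nn.no_grad():
            f = extract_local_features(np.zeros((1, 3, 32, 32), np.float32), bb)
        assert np.all(f.data == 0.0)

    def test_inference_is_bitwise_deterministic(self):
        bb = ResidualBackbone(micro_config().encoder, np.random.default_rng(0)).eval()
        x = np.random.default_rng(2).normal(size=(2, 3, 32, 32)).astype(np.float32)
        with nn.no_grad():
            a = bb(Tensor(x)).data
            b = bb(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_shape_mismatch_raises_contract_error(self):
        bb = ResidualBackbone(micro_config().encoder, np.random.default_rng(0))
        with pytest.raises(ContractError, match="3, 32, 32"):
            bb(Tensor(np.zeros((1, 3, 64, 64), np.float32)))


class TestBridge:
    @pytest.mark.parametrize("cfg,expected", [
        (EncoderConfig(), (64, 256)),                    # (7-1)*2+4 = 16 -> 64 x 256
        (micro_config().encoder, (4, 16)),               # (1-1)*2+4 = 4  -> 4 x 16
    ])
    def test_bridge_token_geometry(self, cfg, expected):
        assert (cfg.token_count, cfg.token_dim) == expected

    def test_zero_feature_map_isolates_position_embedding(self, rng):
        enc = micro_config().encoder
        from thyfuse.encoder import FeatureEmbedding
        bridge = FeatureEmbedding(enc, rng)
        with nn.no_grad():
            seq = embed_tokens(Tensor(np.zeros((2, 8, 1, 1), np.float32)), bridge)
        np.testing.assert_allclose(
            seq.tokens.data, np.broadcast_to(bridge.position_embedding.data, (2, 4, 16)),
            atol=1e-6)
        assert not seq.has_cls

    def test_zero_position_embedding_gives_flattened_deconv(self, rng):
        enc = micro_config().encoder
        from thyfuse.encoder import FeatureEmbedding
        from thyfuse.nn import functional as F
        bridge = FeatureEmbedding(enc, rng)
        bridge.position_embedding.data[...] = 0.0
        f = Tensor(rng.normal(size=(1, 8, 1, 1)).astype(np.float32))
        with nn.no_grad():
            seq = embed_tokens(f, bridge)
            raw = F.conv_transpose2d(f, bridge.deconv.weight, bridge.deconv.bias,
                                     enc.bridge_stride, enc.bridge_padding)
        np.testing.assert_allclose(seq.tokens.data, raw.data.reshape(1, 4, 16),
                                   atol=1e-6)

    def test_wrong_feature_shape_raises(self, rng):
        from thyfuse.encoder import FeatureEmbedding
        bridge = FeatureEmbedding(micro_config().encoder, rng)
        with pytest.raises(ContractError):
            bridge(Tensor(np.zeros((1, 8, 2, 2), np.float32)))


class TestSelfAttention:
    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            l = int(rng.integers(2, 9))
            d = int(rng.integers(2, 17))
            attn = SelfAttention(d, rng)
            x = rng.normal(size=(2, l, d)).astype(np.float32)
            with nn.no_grad():
                got = attn(Tensor(x)).data
            np.testing.assert_allclose(got, loop_self_attention(x, attn), atol=1e-5)

    def test_single_token_returns_its_value_projection(self, rng):
        attn = SelfAttention(8, rng)
        x = rng.normal(size=(1, 1, 8)).astype(np.float32)
        with nn.no_grad():
            got = intra_self_attention(TokenSequence(Tensor(x)), attn)
            h = attn.norm(Tensor(x))
            v = attn.value_proj(h)
        np.testing.assert_allclose(got.tokens.data, v.data, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        attn = SelfAttention(16, rng)
        with nn.no_grad():
            attn(Tensor(rng.normal(size=(3, 7, 16)).astype(np.float32)))
        np.testing.assert_allclose(attn.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_non_finite_input_raises_numeric_error(self, rng):
        attn = SelfAttention(4, rng)
        bad = np.zeros((1, 2, 4), np.float32)
        bad[0, 0, 0] = np.nan
        with pytest.raises(NumericError):
            attn(Tensor(bad))


class TestTransformerBlock:
    def test_zero_weight_block_is_identity(self, rng):
        block = TransformerBlock(16, 2, SelfAttention(16, rng), rng)
        zero_linears(block)
        x = rng.normal(size=(2, 4, 16)).astype(np.float32)
        with nn.no_grad():
            out = intra_transformer_block(TokenSequence(Tensor(x)), block)
        assert np.array_equal(out.tokens.data, x)

    def test_stack_of_zero_blocks_is_identity(self, rng):
        blocks = [TransformerBlock(16, 2, SelfAttention(16, rng), rng)
                  for _ in range(4)]
        for b in blocks:
            zero_linears(b)
        x = rng.normal(size=(1, 4, 16)).astype(np.float32)
        t = Tensor(x)
        with nn.no_grad():
            for b in blocks:
                t = b(t)
        assert np.array_equal(t.data, x)

    def test_output_shape_equals_input_shape(self, rng):
        block = TransformerBlock(16, 4, SelfAttention(16, rng), rng)
        x = Tensor(rng.normal(size=(3, 5, 16)).astype(np.float32))
        with nn.no_grad():
            assert block(x).shape == x.shape


class TestEncodeModality:
    @pytest.mark.parametrize("orientation,expected", [
        ("channels", (4, 16)), ("positions", (16, 4)),
    ])
    def test_token_geometry_by_orientation(self, orientation, expected, rng):
        cfg = micro_config(orientation=orientation).encoder
        enc = HybridSingleModalEncoder(cfg, rng).eval()
        with nn.no_grad():
            seq = encode_modality(rng.normal(size=(2, 3, 32, 32)).astype(np.float32), enc)
        assert (seq.length, seq.dim) == expected

    def test_branches_hold_disjoint_parameters(self, rng):
        cfg = micro_config().encoder
        us = HybridSingleModalEncoder(cfg, np.random.default_rng(0)).eval()
        irt = HybridSingleModalEncoder(cfg, np.random.default_rng(1)).eval()
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        with nn.no_grad():
            before = irt(x).tokens.data.copy()
        for p in us.parameters():
            p.data[...] = 0.0
        with nn.no_grad():
            after = irt(x).tokens.data
        assert np.array_equal(before, after)

    def test_every_parameter_receives_gradient(self, rng):
        enc = HybridSingleModalEncoder(micro_config().encoder, rng)
        head = nn.Linear(16, 2, rng)
        x = rng.normal(size=(8, 3, 32, 32)).astype(np.float32)
        labels = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        seq = enc(x)
        loss = nn.cross_entropy(head(seq.tokens.mean(axis=1)), labels)
        loss.backward()
        for name, p in enc.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_pretrained_flag_is_rejected(self):
        cfg = micro_config().encoder
        from dataclasses import replace
        with pytest.raises(ConfigError, match="pretrained"):
            HybridSingleModalEncoder(replace(cfg, pretrained=True),
                                     np.random.default_rng(0))
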