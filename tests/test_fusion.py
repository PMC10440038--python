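"""Adaptive weight network and cross-modal encoder: simplex contract,
assembly arithmetic, multi-head attention oracle, fusion contracts."""

import numpy as np
import pytest

from thyfuse import nn
from thyfuse.config import FusionConfig
from thyfuse.encoder import SelfAttention, TokenSequence, TransformerBlock
from thyfuse.errors import ConfigError, ContractError
from thyfuse.fusion import (AdaptiveWeightNetwork, CrossModalFuser, ModalityWeights,
                            MultiHeadSelfAttention, assemble_fusion_tokens, fuse,
                            generate_modality_weights)
from thyfuse.nn import Tensor

from conftest import micro_config

L, D = 4, 16


def seqs(rng, batch=3):
    a = TokenSequence(Tensor(rng.normal(size=(batch, L, D)).astype(np.float32)))
    b = TokenSequence(Tensor(rng.normal(size=(batch, L, D)).astype(np.float32)))
    return a, b


class TestWeightNetwork:
    def test_weights_land_on_simplex(self, rng):
        amwg = AdaptiveWeightNetwork(L, D, micro_config().fusion, rng)
        for _ in range(20):
            f_us, f_irt = seqs(rng, batch=5)
            with nn.no_grad():
                w = generate_modality_weights(f_us, f_irt, amwg)
            s = w.values.data.sum(axis=1)
            np.testing.assert_allclose(s, 1.0, atol=1e-6)
            assert (w.values.data >= 0).all()

    def test_zeroed_final_layer_gives_equal_weights(self, rng):
        amwg = AdaptiveWeightNetwork(L, D, micro_config().fusion, rng)
        amwg.fc3.weight.data[...] = 0.0
        amwg.fc3.bias.data[...] = 0.0
        f_us, f_irt = seqs(rng)
        with nn.no_grad():
            w = amwg(f_us, f_irt)
        np.testing.assert_allclose(w.values.data, 0.5, atol=1e-7)

    def test_forced_log2_logit_gives_two_thirds(self, rng):
        amwg = AdaptiveWeightNetwork(L, D, micro_config().fusion, rng)
        amwg.fc3.weight.data[...] = 0.0
        amwg.fc3.bias.data = np.array([np.log(2.0), 0.0], dtype=np.float32)
        f_us, f_irt = seqs(rng)
        with nn.no_grad():
            w = amwg(f_us, f_irt)
        np.testing.assert_allclose(w.values.data[:, 0], 2.0 / 3.0, atol=1e-6)
        np.testing.assert_allclose(w.values.data[:, 1], 1.0 / 3.0, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        amwg = AdaptiveWeightNetwork(L, D, micro_config().fusion, rng)
        a = TokenSequence(Tensor(np.zeros((2, L, D), np.float32)))
        b = TokenSequence(Tensor(np.zeros((2, L + 1, D), np.float32)))
        with pytest.raises(ContractError):
            amwg(a, b)

    def test_amwg_parameters_receive_gradient(self, rng):
        amwg = AdaptiveWeightNetwork(L, D, micro_config().fusion, rng)
        f_us = TokenSequence(Tensor(rng.normal(size=(4, L, D)).astype(np.float32)))
        f_irt = TokenSequence(Tensor(rng.normal(size=(4, L, D)).astype(np.float32)))
        w = amwg(f_us, f_irt)
        # loss that prefers one modality: drive w_us up
        loss = ((w.values[:, 0] - 1.0) * (w.values[:, 0] - 1.0)).sum()
        loss.backward()
        for name, p in amwg.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestAssembly:
    def test_endpoint_weight_selects_one_modality(self, rng):
        f_us, f_irt = seqs(rng)
        w = ModalityWeights(Tensor(np.tile([1.0, 0.0], (3, 1)).astype(np.float32)))
        cls = Tensor(np.zeros((1, 1, D), np.float32))
        pe = Tensor(np.zeros((L + 1, D), np.float32))
        out = assemble_fusion_tokens(f_us, f_irt, w, cls, pe)
        np.testing.assert_allclose(out.tokens.data[:, 1:], f_us.tokens.data, atol=1e-7)

    def test_half_half_weight_is_elementwise_mean(self, rng):
        f_us, f_irt = seqs(rng)
        w = ModalityWeights.fixed(3)
        cls = Tensor(np.zeros((1, 1, D), np.float32))
        pe = Tensor(np.zeros((L + 1, D), np.float32))
        out = assemble_fusion_tokens(f_us, f_irt, w, cls, pe)
        np.testing.assert_allclose(
            out.tokens.data[:, 1:],
            0.5 * (f_us.tokens.data + f_irt.tokens.data), atol=1e-7)

    def test_shape_bookkeeping_with_cls(self, rng):
        c, dim = 4, 9
        a = TokenSequence(Tensor(rng.normal(size=(2, c, dim)).astype(np.float32)))
        b = TokenSequence(Tensor(rng.normal(size=(2, c, dim)).astype(np.float32)))
        cls = Tensor(rng.normal(size=(1, 1, dim)).astype(np.float32))
        pe = Tensor(np.zeros((c + 1, dim), np.float32))
        out = assemble_fusion_tokens(a, b, ModalityWeights.fixed(2), cls, pe)
        assert out.tokens.shape == (2, c + 1, dim)
        assert out.has_cls
        np.testing.assert_allclose(out.tokens.data[:, 0],
                                   np.tile(cls.data[0, 0], (2, 1)), atol=1e-7)

    def test_swapping_modalities_and_weights_preserves_body(self, rng):
        f_us, f_irt = seqs(rng)
        w = ModalityWeights(Tensor(np.tile([0.8, 0.2], (3, 1)).astype(np.float32)))
        w_swap = ModalityWeights(Tensor(np.tile([0.2, 0.8], (3, 1)).astype(np.float32)))
        cls = Tensor(np.zeros((1, 1, D), np.float32))
        pe = Tensor(np.zeros((L + 1, D), np.float32))
        a = assemble_fusion_tokens(f_us, f_irt, w, cls, pe)
        b = assemble_fusion_tokens(f_irt, f_us, w_swap, cls, pe)
        np.testing.assert_allclose(a.tokens.data, b.tokens.data, atol=1e-6)


class TestMultiHeadAttention:
    def test_one_head_with_identity_output_equals_single_head(self, rng):
        sa = SelfAttention(D, rng)
        msa = MultiHeadSelfAttention(D, 1, rng)
        # share normalization and projection parameters across the two paths
        for src, dst in ((sa.norm, msa.norm), (sa.query_proj, msa.query_proj),
                         (sa.key_proj, msa.key_proj), (sa.value_proj, msa.value_proj)):
            dst.weight.data = src.weight.data.copy()
            dst.bias.data = src.bias.data.copy()
        msa.out_proj.weight.data = np.eye(D, dtype=np.float32)
        msa.out_proj.bias.data[...] = 0.0
        x = Tensor(rng.normal(size=(2, 5, D)).astype(np.float32))
        with nn.no_grad():
            np.testing.assert_allclose(msa(x).data, sa(x).data, atol=1e-5)

    def test_per_head_rows_sum_to_one(self, rng):
        msa = MultiHeadSelfAttention(D, 4, rng)
        with nn.no_grad():
            msa(Tensor(rng.normal(size=(2, 6, D)).astype(np.float32)))
        np.testing.assert_allclose(msa.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_head_dim_split(self):
        msa = MultiHeadSelfAttention(256, 8, np.random.default_rng(0))
        assert msa.head_dim == 32

    def test_indivisible_head_count_is_rejected(self):
        with pytest.raises(ConfigError):
            MultiHeadSelfAttention(10, 4, np.random.default_rng(0))


class TestFuse:
    def test_zero_blocks_return_cls_plus_its_pe_slot(self, rng):
        fuser = CrossModalFuser(L, D, micro_config().fusion, rng)
        for block in fuser.blocks:
            for m in block.modules():
                if isinstance(m, nn.Linear):
                    m.weight.data[...] = 0.0
                    if m.bias is not None:
                        m.bias.data[...] = 0.0
        f_us, f_irt = seqs(rng)
        with nn.no_grad():
            out = fuse(f_us, f_irt, fuser, ModalityWeights.fixed(3))
        expected = fuser.cls_token.data[0, 0] + fuser.position_embedding.data[0]
        np.testing.assert_allclose(out.data, np.tile(expected, (3, 1)), atol=1e-7)

    def test_output_dim_is_token_dim(self, rng):
        fuser = CrossModalFuser(L, D, micro_config().fusion, rng)
        f_us, f_irt = seqs(rng)
        with nn.no_grad():
            out = fuse(f_us, f_irt, fuser, ModalityWeights.fixed(3))
        assert out.shape == (3, D)

    def test_fusion_is_asymmetric_under_unequal_weights(self, rng):
        fuser = CrossModalFuser(L, D, micro_config().fusion, rng)
        f_us, f_irt = seqs(rng)
        w = ModalityWeights(Tensor(np.tile([0.9, 0.1], (3, 1)).astype(np.float32)))
        with nn.no_grad():
            a = fuse(f_us, f_irt, fuser, w)
            b = fuse(f_irt, f_us, fuser, w)
        assert not np.allclose(a.data, b.data, atol=1e-4)
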