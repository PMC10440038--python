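"""Adaptive fusion of the two modality token sequences.

Two pieces:

* the adaptive modality-weight generation network — a three-linear-layer
  MLP with ReLU activations over the concatenated flattened branch
  features, closed by a softmax so the pair of case-specific weights
  (w_us, w_irt) always lies on the 1-simplex;
* the adaptive cross-modal encoder — the weighted sum of the two token
  sequences is prepended with a learnable *cls* token, given a learnable
  position embedding, and refined by a stack of pre-norm Transformer
  blocks whose attention is multi-headed (8 heads at full scale).  The
  final *cls* embedding is the fused case representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import FusionConfig
from .encoder import TokenSequence, TransformerBlock
from .errors import ConfigError, ContractError, NumericError
from .nn import Tensor

__all__ = [
    "ModalityWeights",
    "AdaptiveWeightNetwork",
    "MultiHeadSelfAttention",
    "CrossModalFuser",
    "generate_modality_weights",
    "assemble_fusion_tokens",
    "multi_head_self_attention",
    "inter_transformer_block",
    "fuse",
]


@dataclass
class ModalityWeights:
    """Per-case convex weights over {US, IRT}; values: (B, 2) on the 1-simplex."""

    values: Tensor

    @property
    def w_us(self) -> np.ndarray:
        return self.values.data[:, 0]

    @property
    def w_irt(self) -> np.ndarray:
        return self.values.data[:, 1]

    @staticmethod
    def fixed(batch: int, w_us: float = 0.5) -> "ModalityWeights":
        vals = np.tile(np.array([w_us, 1.0 - w_us], dtype=np.float32), (batch, 1))
        return ModalityWeights(Tensor(vals))


class AdaptiveWeightNetwork(nn.Module):
    """Three linear layers with ReLU, softmax over the two outputs.

    The final layer starts with small weights so an untrained network
    begins near the neutral (0.5, 0.5) weighting; it is trained end-to-end
    with the rest of the model.
    """

    def __init__(self, token_count: int, token_dim: int, config: FusionConfig,
                 rng: np.random.Generator):
        super().__init__()
        flat = token_count * token_dim
        h1, h2 = config.amwg_hidden
        self.fc1 = nn.Linear(2 * flat, h1, rng, init="he")
        self.fc2 = nn.Linear(h1, h2, rng, init="he")
        self.fc3 = nn.Linear(h2, 2, rng, init="attn")
        self._flat = flat

    def forward(self, f_us: TokenSequence, f_irt: TokenSequence) -> ModalityWeights:
        if f_us.tokens.shape != f_irt.tokens.shape:
            raise ContractError(
                f"modality sequences disagree: {f_us.tokens.shape} vs {f_irt.tokens.shape}"
            )
        b = f_us.tokens.shape[0]
        x = nn.concat([f_us.tokens.reshape(b, self._flat),
                       f_irt.tokens.reshape(b, self._flat)], axis=1)
        x = nn.relu(self.fc1(x))
        x = nn.relu(self.fc2(x))
        logits = self.fc3(x)
        return ModalityWeights(nn.softmax(logits, axis=-1))


class MultiHeadSelfAttention(nn.Module):
    """Pre-norm multi-head scaled dot-product self-attention.

    The token dimension is split across ``heads`` subspaces (d_k = D/heads
    per head); head outputs are concatenated and mixed by the output
    projection W^O.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ConfigError(f"token dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.norm = nn.LayerNorm(dim)
        self.query_proj = nn.Linear(dim, dim, rng, init="attn")
        self.key_proj = nn.Linear(dim, dim, rng, init="attn")
        self.value_proj = nn.Linear(dim, dim, rng, init="attn")
        self.out_proj = nn.Linear(dim, dim, rng, init="attn")
        self.scale = 1.0 / np.sqrt(self.head_dim)
        self.last_attention: np.ndarray | None = None

    def _split(self, t: Tensor, b: int, l: int) -> Tensor:
        return t.reshape(b, l, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise NumericError("non-finite values entering multi-head attention")
        b, l, _ = x.shape
        h = self.norm(x)
        q = self._split(self.query_proj(h), b, l)
        k = self._split(self.key_proj(h), b, l)
        v = self._split(self.value_proj(h), b, l)
        scores = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        attn = nn.softmax(scores, axis=-1)          # (B, H, L, L)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, self.dim)
        return self.out_proj(out)


class CrossModalFuser(nn.Module):
    """Weighted-sum token assembly with *cls* token plus the inter-modal
    Transformer stack; returns the final *cls* embedding."""

    def __init__(self, token_count: int, token_dim: int, config: FusionConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate(token_dim)
        self.token_count = token_count
        self.token_dim = token_dim
        self.cls_token = nn.Parameter(np.zeros((1, 1, token_dim), dtype=np.float32))
        self.position_embedding = nn.Parameter(
            rng.normal(0.0, 0.02, (token_count + 1, token_dim)).astype(np.float32)
        )
        self.blocks = nn.ModuleList(
            TransformerBlock(token_dim, config.mlp_expansion,
                             MultiHeadSelfAttention(token_dim, config.heads, rng), rng)
            for _ in range(config.inter_blocks)
        )

    def assemble(self, f_us: TokenSequence, f_irt: TokenSequence,
                 weights: ModalityWeights) -> TokenSequence:
        return assemble_fusion_tokens(f_us, f_irt, weights, self.cls_token,
                                      self.position_embedding)

    def forward(self, f_us: TokenSequence, f_irt: TokenSequence,
                weights: ModalityWeights) -> Tensor:
        seq = self.assemble(f_us, f_irt, weights)
        x = seq.tokens
        for block in self.blocks:
            x = block(x)
        return x[:, 0, :]                            # fused cls embedding (B, D)


# --------------------------------------------------------------- functional ops

def generate_modality_weights(f_us: TokenSequence, f_irt: TokenSequence,
                              amwg: AdaptiveWeightNetwork) -> ModalityWeights:
    """Case-adaptive convex weights for the two modalities (sum to 1)."""
    return amwg(f_us, f_irt)


def assemble_fusion_tokens(f_us: TokenSequence, f_irt: TokenSequence,
                           weights: ModalityWeights, cls_token: Tensor,
                           position_embedding: Tensor) -> TokenSequence:
    """[cls, w_us*F_us + w_irt*F_irt] + PE, length C''+1, cls first."""
    if f_us.tokens.shape != f_irt.tokens.shape:
        raise ContractError(
            f"modality sequences disagree: {f_us.tokens.shape} vs {f_irt.tokens.shape}"
        )
    b = f_us.tokens.shape[0]
    w_us = weights.values[:, 0:1].reshape(b, 1, 1)
    w_irt = weights.values[:, 1:2].reshape(b, 1, 1)
    body = w_us * f_us.tokens + w_irt * f_irt.tokens
    cls = cls_token.broadcast_to((b,) + tuple(cls_token.shape[1:]))
    tokens = nn.concat([cls, body], axis=1) + position_embedding
    return TokenSequence(tokens, has_cls=True)


def multi_head_self_attention(seq: TokenSequence,
                              attention: MultiHeadSelfAttention) -> TokenSequence:
    return TokenSequence(attention(seq.tokens), has_cls=seq.has_cls)


def inter_transformer_block(seq: TokenSequence, block: TransformerBlock) -> TokenSequence:
    return TokenSequence(block(seq.tokens), has_cls=seq.has_cls)


def fuse(f_us: TokenSequence, f_irt: TokenSequence, fuser: CrossModalFuser,
         weights: ModalityWeights) -> Tensor:
    """Full fusion path; returns the final cls embedding (B, D)."""
    return fuser(f_us, f_irt, weights)
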