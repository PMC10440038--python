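"""Hybrid single-modal encoder: residual CNN feature extractor, the
transposed-convolution feature-embedding bridge, and the intra-modal
Transformer stack.

One encoder instance is built per imaging modality (ultrasound /
thermography) with independent parameters.  The CNN supplies local texture
and boundary features; the Transformer blocks on top of the token sequence
supply global context through self-attention.

Token orientation
-----------------
By default the bridge emits *channels as tokens*: C'' tokens, each the
flattened H''xW'' spatial map of one channel (token dim D = H''W'').  The
conventional positions-as-tokens layout is available through
``EncoderConfig.token_orientation = "positions"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import EncoderConfig
from .errors import ConfigError, ContractError, NumericError
from .nn import Tensor

__all__ = [
    "TokenSequence",
    "ResidualBackbone",
    "FeatureEmbedding",
    "PatchEmbedding",
    "SelfAttention",
    "TokenMLP",
    "TransformerBlock",
    "HybridSingleModalEncoder",
    "extract_local_features",
    "embed_tokens",
    "intra_self_attention",
    "intra_transformer_block",
    "encode_modality",
]


@dataclass
class TokenSequence:
    """An ordered batch of token embeddings, shape (B, L, D).

    ``has_cls`` marks sequences assembled for fusion whose first token is
    the learnable classification token.
    """

    tokens: Tensor
    has_cls: bool = False

    @property
    def length(self) -> int:
        return self.tokens.shape[1]

    @property
    def dim(self) -> int:
        return self.tokens.shape[2]


def _as_batched(image) -> Tensor:
    if not isinstance(image, Tensor):
        image = Tensor(np.asarray(image, dtype=np.float32))
    if image.ndim == 3:
        image = image.reshape((1,) + image.shape)
    if image.ndim != 4:
        raise ContractError(f"expected a CxHxW or BxCxHxW image, got shape {image.shape}")
    return image


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return nn.relu(y + skip)


class ResidualBackbone(nn.Module):
    """18-layer-style residual CNN truncated before global pooling.

    With the default widths and a 3x224x224 input the output feature map is
    512x7x7 (total stride 32: stem conv /2, stem pool /2, three /2 stages).
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        c = config.stem_channels
        self.conv1 = nn.Conv2d(config.in_channels, c, 7, rng, stride=2, padding=3,
                               bias=False)
        self.bn1 = nn.BatchNorm2d(c)
        stages = []
        in_ch = c
        for i, (out_ch, depth) in enumerate(zip(config.stage_channels, config.stage_blocks)):
            for j in range(depth):
                stride = 2 if (i > 0 and j == 0) else 1
                stages.append(BasicBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
        self.stages = nn.Sequential(stages)

    def forward(self, image: Tensor) -> Tensor:
        cfg = self.config
        expected = (cfg.in_channels, cfg.input_size, cfg.input_size)
        if tuple(image.shape[1:]) != expected:
            raise ContractError(
                f"backbone expects images of shape {expected}, got {tuple(image.shape[1:])}"
            )
        x = nn.relu(self.bn1(self.conv1(image)))
        x = nn.functional.max_pool2d(x, kernel=3, stride=2, padding=1)
        return self.stages(x)


class FeatureEmbedding(nn.Module):
    """Bridge from the CNN feature map to the Transformer token sequence.

    A learnable transposed convolution resizes the (C',H',W') map to
    (C'',H'',W''); the map is flattened to tokens and a learnable position
    embedding is added element-wise, once, at construction of the sequence.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.deconv = nn.ConvTranspose2d(
            config.feature_channels, config.bridge_channels, config.bridge_kernel, rng,
            stride=config.bridge_stride, padding=config.bridge_padding,
        )
        self.position_embedding = nn.Parameter(
            rng.normal(0.0, 0.02, (config.token_count, config.token_dim)).astype(np.float32)
        )

    def forward(self, f_local: Tensor) -> TokenSequence:
        cfg = self.config
        expected = (cfg.feature_channels, cfg.feature_size, cfg.feature_size)
        if tuple(f_local.shape[1:]) != expected:
            raise ContractError(
                f"bridge expects feature maps of shape {expected}, "
                f"got {tuple(f_local.shape[1:])}"
            )
        maps = self.deconv(f_local)                       # (B, C'', H'', W'')
        b = maps.shape[0]
        sq = cfg.bridge_size * cfg.bridge_size
        tokens = maps.reshape(b, cfg.bridge_channels, sq)  # channels as tokens
        if cfg.token_orientation == "positions":
            tokens = tokens.transpose(0, 2, 1)
        return TokenSequence(tokens + self.position_embedding, has_cls=False)


class PatchEmbedding(nn.Module):
    """ViT-style patch embedding producing the same (L, D) token geometry as
    the bridge, used by the pure-Transformer branch variants."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        grid = round(config.token_count ** 0.5)
        if grid * grid != config.token_count:
            raise ConfigError("patch embedding requires a square token grid")
        patch = config.input_size // grid
        if patch * grid != config.input_size:
            raise ConfigError("input_size must be divisible by the patch grid")
        self.proj = nn.Conv2d(config.in_channels, config.token_dim, patch, rng,
                              stride=patch)
        self.position_embedding = nn.Parameter(
            rng.normal(0.0, 0.02, (config.token_count, config.token_dim)).astype(np.float32)
        )

    def forward(self, image: Tensor) -> TokenSequence:
        cfg = self.config
        expected = (cfg.in_channels, cfg.input_size, cfg.input_size)
        if tuple(image.shape[1:]) != expected:
            raise ContractError(
                f"patch embedding expects images of shape {expected}, "
                f"got {tuple(image.shape[1:])}"
            )
        maps = self.proj(image)                            # (B, D, g, g)
        b, d = maps.shape[0], maps.shape[1]
        tokens = maps.reshape(b, d, cfg.token_count).transpose(0, 2, 1)
        return TokenSequence(tokens + self.position_embedding, has_cls=False)


class SelfAttention(nn.Module):
    """Single-head scaled dot-product self-attention with pre-normalization.

    The key dimension equals the full token dimension (one undivided
    projection).  The row-stochastic attention matrix of the latest call is
    kept in ``last_attention`` for inspection.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.norm = nn.LayerNorm(dim)
        self.query_proj = nn.Linear(dim, dim, rng, init="attn")
        self.key_proj = nn.Linear(dim, dim, rng, init="attn")
        self.value_proj = nn.Linear(dim, dim, rng, init="attn")
        self.scale = 1.0 / np.sqrt(dim)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise NumericError("non-finite values entering self-attention")
        h = self.norm(x)
        q = self.query_proj(h)
        k = self.key_proj(h)
        v = self.value_proj(h)
        scores = (q @ k.transpose(0, 2, 1)) * self.scale
        attn = nn.softmax(scores, axis=-1)
        self.last_attention = attn.data
        return attn @ v


class TokenMLP(nn.Module):
    """The Transformer block feed-forward: two linear layers with GELU."""

    def __init__(self, dim: int, expansion: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(dim, dim * expansion, rng, init="attn")
        self.fc2 = nn.Linear(dim * expansion, dim, rng, init="attn")

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(nn.gelu(self.fc1(x)))


class TransformerBlock(nn.Module):
    """Pre-norm residual block: x + Attn(LN(x)), then x + MLP(LN(x)).

    ``attention`` is either a single-head :class:`SelfAttention` (intra-
    modal) or a :class:`~thyfuse.fusion.MultiHeadSelfAttention` (inter-
    modal); both normalize their own input.
    """

    def __init__(self, dim: int, expansion: int, attention: nn.Module,
                 rng: np.random.Generator):
        super().__init__()
        self.attention = attention
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = TokenMLP(dim, expansion, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.attention(x) + x
        return self.mlp(self.norm2(x)) + x


class HybridSingleModalEncoder(nn.Module):
    """One encoder branch.

    mode:
      * ``"hybrid"`` — CNN extractor + bridge + intra-modal Transformer stack;
      * ``"conv"``   — CNN extractor + bridge only (pure-CNN ablation);
      * ``"vit"``    — patch embedding + Transformer stack (pure-Transformer
        ablation).
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 mode: str = "hybrid"):
        super().__init__()
        if mode not in ("hybrid", "conv", "vit"):
            raise ConfigError(f"unknown encoder mode {mode!r}")
        config.validate()
        self.config = config
        self.mode = mode
        dim = config.token_dim
        if mode in ("hybrid", "conv"):
            self.backbone = ResidualBackbone(config, rng)
            self.bridge = FeatureEmbedding(config, rng)
        else:
            self.patch_embed = PatchEmbedding(config, rng)
        if mode in ("hybrid", "vit"):
            self.blocks = nn.ModuleList(
                TransformerBlock(dim, config.mlp_expansion, SelfAttention(dim, rng), rng)
                for _ in range(config.intra_blocks)
            )
        else:
            self.blocks = nn.ModuleList()

    def forward(self, image) -> TokenSequence:
        image = _as_batched(image)
        if self.mode == "vit":
            seq = self.patch_embed(image)
        else:
            seq = self.bridge(self.backbone(image))
        x = seq.tokens
        for block in self.blocks:
            x = block(x)
        return TokenSequence(x, has_cls=False)


# --------------------------------------------------------------- functional ops

def extract_local_features(image, backbone: ResidualBackbone) -> Tensor:
    """Run the truncated residual CNN: (B,C,H,W) -> (B,C',H',W')."""
    return backbone(_as_batched(image))


def embed_tokens(f_local: Tensor, bridge: FeatureEmbedding) -> TokenSequence:
    """Bridge a CNN feature map to a positional-embedded token sequence."""
    return bridge(f_local)


def intra_self_attention(seq: TokenSequence, attention: SelfAttention) -> TokenSequence:
    """Apply single-head self-attention (with its pre-normalization)."""
    return TokenSequence(attention(seq.tokens), has_cls=seq.has_cls)


def intra_transformer_block(seq: TokenSequence, block: TransformerBlock) -> TokenSequence:
    """Apply one pre-norm residual Transformer block."""
    return TokenSequence(block(seq.tokens), has_cls=seq.has_cls)


def encode_modality(image, encoder: HybridSingleModalEncoder) -> TokenSequence:
    """Full branch: local features -> token embedding -> Transformer stack."""
    return encoder(image)
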