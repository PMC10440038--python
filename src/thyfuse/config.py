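"""Architecture and training configuration.

The default geometry follows the published design: 224x224 inputs, an
18-layer residual backbone truncated before global pooling (512x7x7
feature maps), a transposed-convolution bridge to 64 tokens of dimension
256, four intra-modal Transformer blocks per branch, and an inter-modal
Transformer with 8 heads.  ``desk_scale_config`` returns a proportionally
shrunk geometry used by the test suite and the examples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

from .errors import ConfigError

__all__ = [
    "EncoderConfig", "FusionConfig", "ModelConfig", "TrainConfig",
    "desk_scale_config", "config_from_dict",
]

VARIANTS = (
    "ammh",
    "hybrid_single_us",
    "hybrid_single_irt",
    "hybrid_wo_acme",
    "resnet_wo_acme",
    "vit_wo_acme",
    "resnet_w_acme",
    "vit_w_acme",
    "ammh_wo_amwg",
)


@dataclass
class EncoderConfig:
    """Geometry of one hybrid single-modal encoder branch."""

    in_channels: int = 3
    input_size: int = 224
    stem_channels: int = 64
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    stage_blocks: tuple[int, ...] = (2, 2, 2, 2)
    bridge_channels: int = 64          # C'': number of tokens (channel orientation)
    bridge_kernel: int = 4
    bridge_stride: int = 2
    bridge_padding: int = 0
    intra_blocks: int = 4
    mlp_expansion: int = 4
    token_orientation: str = "channels"   # "channels" | "positions"
    pretrained: bool = False

    # ----------------------------------------------------------- derived dims
    @property
    def feature_channels(self) -> int:      # C'
        return self.stage_channels[-1]

    @property
    def feature_size(self) -> int:          # H' = W' (total stride 32)
        return self.input_size // 32

    @property
    def bridge_size(self) -> int:           # H'' = W''
        return ((self.feature_size - 1) * self.bridge_stride
                + self.bridge_kernel - 2 * self.bridge_padding)

    @property
    def token_count(self) -> int:
        if self.token_orientation == "channels":
            return self.bridge_channels
        return self.bridge_size * self.bridge_size

    @property
    def token_dim(self) -> int:
        if self.token_orientation == "channels":
            return self.bridge_size * self.bridge_size
        return self.bridge_channels

    def validate(self) -> None:
        if self.input_size % 32 != 0:
            raise ConfigError(f"input_size {self.input_size} must be a multiple of 32")
        if len(self.stage_channels) != len(self.stage_blocks):
            raise ConfigError("stage_channels and stage_blocks must have equal length")
        if self.intra_blocks < 1:
            raise ConfigError("intra_blocks must be >= 1")
        if self.bridge_size < 1:
            raise ConfigError("bridge geometry collapses to an empty map")
        if self.token_orientation not in ("channels", "positions"):
            raise ConfigError(f"unknown token_orientation {self.token_orientation!r}")
        if self.pretrained:
            raise ConfigError("pretrained backbone weights are not distributed "
                              "with this package; set pretrained=false")
        root = round(self.bridge_channels ** 0.5)
        if root * root != self.bridge_channels:
            raise ConfigError("bridge_channels must be a perfect square so the "
                              "pure-Transformer branch can patchify to the same grid")
        if self.input_size % root != 0:
            raise ConfigError("input_size must be divisible by sqrt(bridge_channels) "
                              "for the pure-Transformer patch embedding")


@dataclass
class FusionConfig:
    """Adaptive weight network and cross-modal encoder settings."""

    inter_blocks: int = 4
    heads: int = 8
    amwg_hidden: tuple[int, int] = (256, 64)
    mlp_expansion: int = 4

    def validate(self, token_dim: int) -> None:
        if self.inter_blocks < 1:
            raise ConfigError("inter_blocks must be >= 1")
        if token_dim % self.heads != 0:
            raise ConfigError(
                f"token dim {token_dim} not divisible by head count {self.heads}"
            )
        if len(self.amwg_hidden) != 2:
            raise ConfigError("amwg_hidden must give exactly two hidden widths")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    variant: str = "ammh"
    adapter_hidden: int = 256   # width of the head adapter in the no-fusion variants

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        self.encoder.validate()
        self.fusion.validate(self.encoder.token_dim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"]["stage_channels"] = list(self.encoder.stage_channels)
        d["encoder"]["stage_blocks"] = list(self.encoder.stage_blocks)
        d["fusion"]["amwg_hidden"] = list(self.fusion.amwg_hidden)
        return d


@dataclass
class TrainConfig:
    """Optimization settings (published configuration; epochs=200 there)."""

    batch_size: int = 32
    epochs: int = 200
    lr_init: float = 1e-3
    lr_min: float = 1e-4
    schedule: str = "cosine"
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 5e-4
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.lr_min > self.lr_init:
            raise ConfigError("lr_min must not exceed lr_init")
        if self.schedule != "cosine":
            raise ConfigError(f"unknown schedule {self.schedule!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["betas"] = list(self.betas)
        return d


def desk_scale_config(variant: str = "ammh") -> ModelConfig:
    """A proportionally shrunk geometry for CPU-scale experiments.

    96x96 inputs, a narrow 4-stage residual backbone (32x3x3 features), a
    bridge to 16 tokens of dimension 64, depth 2 intra- and inter-modal
    blocks, 4 attention heads.
    """
    enc = EncoderConfig(
        input_size=96,
        stem_channels=8,
        stage_channels=(8, 16, 24, 32),
        stage_blocks=(1, 1, 1, 1),
        bridge_channels=16,
        bridge_kernel=4,
        bridge_stride=2,
        bridge_padding=0,
        intra_blocks=2,
        mlp_expansion=2,
    )
    fus = FusionConfig(inter_blocks=2, heads=4, mlp_expansion=2)
    cfg = ModelConfig(encoder=enc, fusion=fus, variant=variant)
    cfg.validate()
    return cfg


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def config_from_dict(d: dict) -> ModelConfig:
    """Rebuild a ModelConfig from a plain (e.g. YAML-loaded) mapping."""
    enc = EncoderConfig(**_tupled(d.get("encoder", {}), ("stage_channels", "stage_blocks")))
    fus = FusionConfig(**_tupled(d.get("fusion", {}), ("amwg_hidden",)))
    cfg = ModelConfig(
        encoder=enc, fusion=fus,
        variant=d.get("variant", "ammh"),
        adapter_hidden=d.get("adapter_hidden", 256),
    )
    cfg.validate()
    return cfg
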