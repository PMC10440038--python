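import numpy as np
import pytest

from thyfuse.config import EncoderConfig, FusionConfig, ModelConfig, desk_scale_config


def micro_config(variant: str = "ammh", orientation: str = "channels") -> ModelConfig:
    """A minimal geometry for fast structural tests: 32x32 inputs, 1x1
    backbone features, 4 tokens of dimension 16, depth-1 stacks, 4 heads."""
    enc = EncoderConfig(
        input_size=32,
        stem_channels=4,
        stage_channels=(4, 4, 8, 8),
        stage_blocks=(1, 1, 1, 1),
        bridge_channels=4,
        bridge_kernel=4,
        bridge_stride=2,
        bridge_padding=0,
        intra_blocks=1,
        mlp_expansion=2,
        token_orientation=orientation,
    )
    fus = FusionConfig(inter_blocks=1, heads=4, amwg_hidden=(16, 8), mlp_expansion=2)
    cfg = ModelConfig(encoder=enc, fusion=fus, variant=variant)
    cfg.validate()
    return cfg


@pytest.fixture
def micro_cfg():
    return micro_config()


@pytest.fixture
def desk_cfg():
    return desk_scale_config()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
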