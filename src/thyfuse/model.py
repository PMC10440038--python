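"""Assembly of encoder branches, adaptive fusion and the classifier head
into the nine experiment variants, plus checkpointing and complexity
counting.

Variant ids
-----------
========================  =====================================================
``ammh``                  full model: two hybrid branches, adaptive weights,
                          cross-modal Transformer fusion
``hybrid_single_us``      one hybrid branch on ultrasound only
``hybrid_single_irt``     one hybrid branch on thermography only
``hybrid_wo_acme``        two hybrid branches, features concatenated (no
                          cross-modal encoder, no weight network)
``resnet_wo_acme``        pure-CNN branches, concatenated
``vit_wo_acme``           pure-Transformer branches, concatenated
``resnet_w_acme``         pure-CNN branches with adaptive fusion
``vit_w_acme``            pure-Transformer branches with adaptive fusion
``ammh_wo_amwg``          full model with the weight network removed; the two
                          modalities are fixed at (0.5, 0.5)
========================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import VARIANTS, ModelConfig, config_from_dict
from .encoder import HybridSingleModalEncoder, TokenSequence, _as_batched
from .errors import ConfigError, ContractError, NumericError
from .fusion import AdaptiveWeightNetwork, CrossModalFuser, ModalityWeights
from .nn import Tensor

__all__ = ["Prediction", "FusionClassifier", "build_variant", "classify",
           "count_parameters", "save_checkpoint", "load_checkpoint"]

LABELS = ("benign", "malignant")

_BRANCH_MODE = {
    "ammh": "hybrid", "hybrid_single_us": "hybrid", "hybrid_single_irt": "hybrid",
    "hybrid_wo_acme": "hybrid", "ammh_wo_amwg": "hybrid",
    "resnet_wo_acme": "conv", "resnet_w_acme": "conv",
    "vit_wo_acme": "vit", "vit_w_acme": "vit",
}
_SINGLE = {"hybrid_single_us": "us", "hybrid_single_irt": "irt"}
_WITH_ACME = {"ammh", "resnet_w_acme", "vit_w_acme", "ammh_wo_amwg"}
_WITH_AMWG = {"ammh", "resnet_w_acme", "vit_w_acme"}


@dataclass
class Prediction:
    """Classifier output for one case."""

    logits: np.ndarray          # (2,)
    class_probs: np.ndarray     # (2,), sums to 1
    predicted_label: str        # "benign" | "malignant"


class _Head(nn.Module):
    """Classifier head: layer norm + one linear map to the 2 classes."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(dim)
        self.fc = nn.Linear(dim, 2, rng, init="attn")

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.norm(x))


class _ConcatAdapter(nn.Module):
    """Two-layer adapter folding concatenated branch features down to the
    token dimension, keeping head capacity comparable across variants."""

    def __init__(self, flat: int, hidden: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(flat, hidden, rng, init="he")
        self.fc2 = nn.Linear(hidden, dim, rng, init="he")

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(x)))


class FusionClassifier(nn.Module):
    """A buildable, trainable instance of one model variant."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.variant = config.variant
        mode = _BRANCH_MODE[self.variant]
        enc = config.encoder
        l, d = enc.token_count, enc.token_dim
        single = _SINGLE.get(self.variant)

        if single != "irt":
            self.us_branch = HybridSingleModalEncoder(enc, rng, mode)
        if single != "us":
            self.irt_branch = HybridSingleModalEncoder(enc, rng, mode)

        if self.variant in _WITH_AMWG:
            self.amwg = AdaptiveWeightNetwork(l, d, config.fusion, rng)
        if self.variant in _WITH_ACME:
            self.fuser = CrossModalFuser(l, d, config.fusion, rng)
        else:
            flat = (1 if single else 2) * l * d
            self.adapter = _ConcatAdapter(flat, config.adapter_hidden, d, rng)
        self.head = _Head(d, rng)
        self.last_weights: ModalityWeights | None = None

    # ------------------------------------------------------------------ forward
    def forward(self, us=None, irt=None) -> Tensor:
        single = _SINGLE.get(self.variant)
        if single == "us":
            if irt is not None:
                raise ContractError(f"variant {self.variant!r} accepts only a US image")
            if us is None:
                raise ContractError("US image required")
            feats = self.us_branch(us)
            emb = self.adapter(feats.tokens.reshape(feats.tokens.shape[0], -1))
        elif single == "irt":
            if us is not None:
                raise ContractError(f"variant {self.variant!r} accepts only an IRT image")
            if irt is None:
                raise ContractError("IRT image required")
            feats = self.irt_branch(irt)
            emb = self.adapter(feats.tokens.reshape(feats.tokens.shape[0], -1))
        else:
            if us is None or irt is None:
                raise ContractError(f"variant {self.variant!r} requires both modalities")
            f_us = self.us_branch(us)
            f_irt = self.irt_branch(irt)
            if self.variant in _WITH_ACME:
                if self.variant in _WITH_AMWG:
                    weights = self.amwg(f_us, f_irt)
                else:
                    weights = ModalityWeights.fixed(f_us.tokens.shape[0])
                self.last_weights = weights
                emb = self.fuser(f_us, f_irt, weights)
            else:
                b = f_us.tokens.shape[0]
                flat = nn.concat([f_us.tokens.reshape(b, -1),
                                  f_irt.tokens.reshape(b, -1)], axis=1)
                emb = self.adapter(flat)
        logits = self.head(emb)
        if not np.isfinite(logits.data).all():
            raise NumericError("non-finite logits emitted by the classifier head")
        return logits


def build_variant(config: ModelConfig | None = None, seed: int = 0,
                  variant: str | None = None) -> FusionClassifier:
    """Construct a trainable model for one variant id.

    ``variant`` overrides ``config.variant`` when given; an unknown id
    raises :class:`~thyfuse.errors.ConfigError` listing the valid ids.
    """
    if config is None:
        config = ModelConfig()
    if variant is not None:
        from dataclasses import replace
        config = replace(config, variant=variant)
    if config.variant not in VARIANTS:
        raise ConfigError(f"unknown variant {config.variant!r}; one of {VARIANTS}")
    rng = np.random.default_rng(seed)
    return FusionClassifier(config, rng)


def classify(us_image=None, irt_image=None, model: FusionClassifier = None):
    """Inference-mode classification of one pair (or a batch of pairs).

    Returns a single :class:`Prediction` for unbatched input, otherwise an
    order-preserving list of predictions.
    """
    if model is None:
        raise ContractError("a built model is required")
    unbatched = False
    for img in (us_image, irt_image):
        if img is not None and np.asarray(img).ndim == 3:
            unbatched = True
    kwargs = {}
    if us_image is not None:
        kwargs["us"] = _as_batched(us_image)
    if irt_image is not None:
        kwargs["irt"] = _as_batched(irt_image)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            logits = model(**kwargs)
    finally:
        model.train(was_training)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    preds = [
        Prediction(logits=logits.data[i].copy(), class_probs=probs[i].copy(),
                   predicted_label=LABELS[int(probs[i].argmax())])
        for i in range(probs.shape[0])
    ]
    return preds[0] if unbatched and len(preds) == 1 else preds


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars in a module."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: FusionClassifier, path, seed: int = 0) -> None:
    """Single-file archive: parameters + buffers + resolved config + variant + seed."""
    meta = json.dumps({"config": model.config.to_dict(),
                       "variant": model.variant, "seed": seed})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> FusionClassifier:
    """Rebuild a bit-identical model from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = config_from_dict(meta["config"])
    model = build_variant(config, seed=meta["seed"])
    model.load_state_dict(state)
    return model
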