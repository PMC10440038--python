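"""Training and evaluation.

Optimization follows the published protocol: Adam (betas 0.9/0.999,
weight decay 5e-4) minimizing categorical cross-entropy under a cosine
learning-rate decay from 1e-3 to 1e-4.  Model selection keeps the
checkpoint with the best validation F1.  Evaluation reports the six
standard confusion-matrix metrics with malignant as the positive class:

    ACC = (TP+TN)/N        SEN = TP/(TP+FN)      PRE = TP/(TP+FP)
    SPE = TN/(TN+FP)       F_b = (1+b^2) PRE SEN / (b^2 PRE + SEN), b in {1,2}

Inputs are scaled to [0, 1] at rendering time and standardized per channel
by mean/std computed on the training partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import TrainConfig
from .data import ArrayDataset
from .errors import ContractError, NumericError
from .model import LABELS, FusionClassifier, _SINGLE

logger = logging.getLogger("thyfuse")

__all__ = ["MetricSet", "EvalRecord", "Normalizer", "cosine_lr",
           "confusion_metrics", "train", "evaluate"]


@dataclass
class MetricSet:
    """The six evaluation metrics, each in [0, 1].  ``undefined`` lists
    metrics whose denominator was zero (reported as 0)."""

    acc: float
    sen: float
    pre: float
    spe: float
    f1: float
    f2: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("acc", "sen", "pre", "spe", "f1", "f2")}


@dataclass
class EvalRecord:
    case_id: str
    prob_benign: float
    prob_malignant: float
    predicted_label: str
    true_label: str


@dataclass
class Normalizer:
    """Per-channel standardization statistics fit on the training partition."""

    us_mean: np.ndarray
    us_std: np.ndarray
    irt_mean: np.ndarray
    irt_std: np.ndarray

    @staticmethod
    def fit(ds: ArrayDataset) -> "Normalizer":
        def stats(x):
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64).astype(np.float32)
            std = x.std(axis=(0, 2, 3), dtype=np.float64).astype(np.float32)
            return mean.reshape(3, 1, 1), np.maximum(std, 1e-6).reshape(3, 1, 1)

        um, us = stats(ds.us)
        im, istd = stats(ds.irt)
        return Normalizer(um, us, im, istd)

    def us_apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.us_mean) / self.us_std

    def irt_apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.irt_mean) / self.irt_std

    def to_dict(self) -> dict:
        return {k: getattr(self, k).ravel().tolist()
                for k in ("us_mean", "us_std", "irt_mean", "irt_std")}

    @staticmethod
    def from_dict(d: dict) -> "Normalizer":
        return Normalizer(**{k: np.asarray(v, dtype=np.float32).reshape(3, 1, 1)
                             for k, v in d.items()})


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """lr(e) = lr_min + (lr_init - lr_min) (1 + cos(pi e/(E-1))) / 2."""
    if not 0 <= epoch < config.epochs:
        raise ContractError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr_init
    span = config.lr_init - config.lr_min
    return config.lr_min + 0.5 * span * (1.0 + np.cos(np.pi * epoch / (config.epochs - 1)))


def _as_binary(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "US":
        return np.array([1 if v == "malignant" else 0 for v in arr], dtype=np.int64)
    return arr.astype(np.int64)


def confusion_metrics(labels, predictions) -> MetricSet:
    """Six metrics from binary labels/predictions (malignant = positive = 1).

    Zero-denominator ratios are reported as 0 and flagged in ``undefined``.
    """
    y = _as_binary(labels)
    p = _as_binary(predictions)
    if y.size == 0:
        raise ContractError("empty label vector")
    if y.shape != p.shape:
        raise ContractError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / y.size
    sen = ratio(tp, tp + fn, "sen")
    pre = ratio(tp, tp + fp, "pre")
    spe = ratio(tn, tn + fp, "spe")
    f1 = ratio(2.0 * pre * sen, pre + sen, "f1")
    f2 = ratio(5.0 * pre * sen, 4.0 * pre + sen, "f2")
    return MetricSet(acc, sen, pre, spe, f1, f2, tuple(undefined))


def _model_inputs(model: FusionClassifier, us: np.ndarray, irt: np.ndarray) -> dict:
    single = _SINGLE.get(model.variant)
    if single == "us":
        return {"us": nn.Tensor(us)}
    if single == "irt":
        return {"irt": nn.Tensor(irt)}
    return {"us": nn.Tensor(us), "irt": nn.Tensor(irt)}


def _forward_logits(model, norm, ds, idx, batch_size):
    """Inference pass over ds[idx]; returns logits array (n, 2)."""
    outs = []
    with nn.no_grad():
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo:lo + batch_size]
            kwargs = _model_inputs(model, norm.us_apply(ds.us[sel]),
                                   norm.irt_apply(ds.irt[sel]))
            outs.append(model(**kwargs).data)
    return np.concatenate(outs, axis=0)


def train(model: FusionClassifier, train_part: ArrayDataset, val_part: ArrayDataset,
          config: TrainConfig) -> tuple[FusionClassifier, list[dict]]:
    """Train in place; returns the model restored to its best-validation-F1
    state and the per-epoch history."""
    config.validate()
    if len(train_part) == 0 or len(val_part) == 0:
        raise ContractError("training and validation partitions must be non-empty")
    norm = Normalizer.fit(train_part)
    model.normalizer = norm
    opt = nn.Adam(model.parameters(), lr=config.lr_init, betas=config.betas,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = len(train_part)
    history: list[dict] = []
    best_f1 = -1.0
    best_state = None

    for epoch in range(config.epochs):
        opt.lr = cosine_lr(epoch, config)
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            kwargs = _model_inputs(model, norm.us_apply(train_part.us[sel]),
                                   norm.irt_apply(train_part.irt[sel]))
            opt.zero_grad()
            loss = nn.cross_entropy(model(**kwargs), train_part.labels[sel])
            if not np.isfinite(loss.data):
                raise NumericError(f"training diverged (non-finite loss) at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        model.eval()
        idx = np.arange(len(val_part))
        logits = _forward_logits(model, norm, val_part, idx, config.batch_size)
        with nn.no_grad():
            val_loss = float(nn.cross_entropy(nn.Tensor(logits), val_part.labels).data)
        val_metrics = confusion_metrics(val_part.labels, logits.argmax(axis=1))
        history.append({
            "epoch": epoch,
            "lr": float(opt.lr),
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_metrics": val_metrics,
        })
        logger.info("epoch %d lr %.2e train_loss %.4f val_loss %.4f val_f1 %.4f",
                    epoch, opt.lr, history[-1]["train_loss"], val_loss, val_metrics.f1)
        if val_metrics.f1 > best_f1:
            best_f1 = val_metrics.f1
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(model: FusionClassifier, test_part: ArrayDataset,
             batch_size: int = 64) -> tuple[MetricSet, list[EvalRecord], dict]:
    """Inference over a partition.

    Returns the metric set, per-case records, and extras: for variants with
    the adaptive weight network, the mean generated (w_us, w_irt) over the
    partition.
    """
    norm = getattr(model, "normalizer", None)
    if norm is None:
        raise ContractError("model has no normalization statistics; train it "
                            "first or attach a Normalizer")
    model.eval()
    idx = np.arange(len(test_part))
    outs, weights = [], []
    with nn.no_grad():
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo:lo + batch_size]
            kwargs = _model_inputs(model, norm.us_apply(test_part.us[sel]),
                                   norm.irt_apply(test_part.irt[sel]))
            model.last_weights = None
            outs.append(model(**kwargs).data)
            if model.last_weights is not None:
                weights.append(model.last_weights.values.data)
    logits = np.concatenate(outs, axis=0)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    preds = probs.argmax(axis=1)
    records = [
        EvalRecord(case_id=test_part.case_ids[i],
                   prob_benign=float(probs[i, 0]), prob_malignant=float(probs[i, 1]),
                   predicted_label=LABELS[int(preds[i])],
                   true_label=LABELS[int(test_part.labels[i])])
        for i in range(len(idx))
    ]
    metrics = confusion_metrics(test_part.labels, preds)
    extras: dict = {}
    if weights:
        mean_w = np.concatenate(weights, axis=0).mean(axis=0)
        extras["mean_weights"] = {"w_us": float(mean_w[0]), "w_irt": float(mean_w[1])}
    return metrics, records, extras
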