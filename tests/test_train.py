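"""Learning-rate schedule, metric formulas with a brute-force oracle,
descent sanity, and evaluation self-consistency."""

import numpy as np
import pytest

from thyfuse.config import TrainConfig, desk_scale_config
from thyfuse.data import render_partitions
from thyfuse.errors import ContractError
from thyfuse.model import build_variant
from thyfuse.synthetic import generate_dataset, stratified_split
from thyfuse.train import (Normalizer, confusion_metrics, cosine_lr, evaluate,
                           train)


def brute_force_metrics(labels, preds):
    """Independent oracle: re-scan the vectors for every confusion cell."""
    tp = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 1)
    tn = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 0)
    fp = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 1)
    fn = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 0)
    div = lambda a, b: a / b if b else 0.0
    acc = div(tp + tn, len(labels))
    sen = div(tp, tp + fn)
    pre = div(tp, tp + fp)
    spe = div(tn, tn + fp)
    f1 = div(2 * pre * sen, pre + sen)
    f2 = div(5 * pre * sen, 4 * pre + sen)
    return acc, sen, pre, spe, f1, f2


class TestCosineSchedule:
    def test_endpoints_match_configured_rates(self):
        cfg = TrainConfig(epochs=200)
        assert cosine_lr(0, cfg) == pytest.approx(1e-3)
        assert cosine_lr(199, cfg) == pytest.approx(1e-4)

    def test_midpoint_is_halfway(self):
        cfg = TrainConfig(epochs=21)
        assert cosine_lr(10, cfg) == pytest.approx(5.5e-4)

    def test_out_of_range_epoch_raises(self):
        with pytest.raises(ContractError):
            cosine_lr(200, TrainConfig(epochs=200))


class TestConfusionMetrics:
    def test_hand_worked_example(self):
        # TP=3, FP=1, FN=2, TN=4
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = confusion_metrics(labels, preds)
        assert m.acc == pytest.approx(0.7)
        assert m.sen == pytest.approx(0.6)
        assert m.pre == pytest.approx(0.75)
        assert m.spe == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-12)
        assert m.f2 == pytest.approx(0.625, abs=1e-12)

    def test_perfect_predictions_score_one(self):
        m = confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            m = confusion_metrics(y, p)
            for got, want in zip(
                    (m.acc, m.sen, m.pre, m.spe, m.f1, m.f2),
                    brute_force_metrics(y.tolist(), p.tolist())):
                assert got == pytest.approx(want, abs=1e-12)

    def test_zero_denominators_are_flagged(self):
        m = confusion_metrics([0, 0, 1], [0, 0, 0])   # no positive predictions
        assert m.pre == 0.0 and m.f1 == 0.0
        assert m.undefined == ("pre", "f1", "f2")

    def test_label_strings_are_accepted(self):
        m = confusion_metrics(["malignant", "benign"], ["malignant", "benign"])
        assert m.acc == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ContractError):
            confusion_metrics([], [])


@pytest.fixture(scope="module")
def tiny_parts():
    reg = stratified_split(generate_dataset(20, 20, (0.0, 0.0, 1.0), seed=41),
                           seed=41)
    return render_partitions(reg, 96)


class TestTraining:
    def test_loss_descends_on_separable_data(self, tiny_parts):
        model = build_variant(desk_scale_config("ammh"), seed=41)
        cfg = TrainConfig(epochs=4, batch_size=8, seed=41)
        model, history = train(model, tiny_parts["train"], tiny_parts["val"], cfg)
        assert len(history) == 4
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_is_seed_deterministic(self, tiny_parts):
        results = []
        for _ in range(2):
            model = build_variant(desk_scale_config("hybrid_single_us"), seed=42)
            cfg = TrainConfig(epochs=2, batch_size=8, seed=42)
            model, history = train(model, tiny_parts["train"], tiny_parts["val"], cfg)
            metrics, _, _ = evaluate(model, tiny_parts["test"])
            results.append((history[-1]["train_loss"], metrics.as_dict()))
        assert results[0] == results[1]

    def test_evaluate_records_are_self_consistent(self, tiny_parts):
        model = build_variant(desk_scale_config("ammh"), seed=43)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=43)
        model, _ = train(model, tiny_parts["train"], tiny_parts["val"], cfg)
        metrics, records, extras = evaluate(model, tiny_parts["test"])
        assert len(records) == len(tiny_parts["test"])
        recomputed = confusion_metrics([r.true_label for r in records],
                                       [r.predicted_label for r in records])
        assert recomputed.as_dict() == metrics.as_dict()
        w = extras["mean_weights"]
        assert w["w_us"] + w["w_irt"] == pytest.approx(1.0, abs=1e-5)

    def test_evaluate_requires_normalization_stats(self, tiny_parts):
        model = build_variant(desk_scale_config("ammh"), seed=44)
        with pytest.raises(ContractError, match="normaliz"):
            evaluate(model, tiny_parts["test"])


class TestNormalizer:
    def test_roundtrip_through_dict(self, tiny_parts):
        norm = Normalizer.fit(tiny_parts["train"])
        back = Normalizer.from_dict(norm.to_dict())
        np.testing.assert_allclose(norm.us_mean, back.us_mean, atol=1e-6)
        np.testing.assert_allclose(norm.irt_std, back.irt_std, atol=1e-6)

    def test_training_partition_standardizes_to_zero_mean_unit_sd(self, tiny_parts):
        norm = Normalizer.fit(tiny_parts["train"])
        z = norm.us_apply(tiny_parts["train"].us)
        assert abs(z.mean()) < 1e-3
        assert abs(z.std() - 1.0) < 1e-2
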