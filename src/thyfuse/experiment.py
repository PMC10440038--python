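"""Experiment orchestration: dataset generation, training, evaluation and
the ablation comparison table, as driven by a single run configuration."""

from __future__ import annotations

import logging
from pathlib import Path

from .config import VARIANTS
from .data import render_partitions
from .errors import ConfigError
from .io import (RunConfig, derive_seed, load_manifest_partitions, load_run_config,
                 write_dataset, write_metrics_table, write_run_report)
from .model import build_variant, load_checkpoint
from .synthetic import generate_dataset, stratified_split
from .train import Normalizer, evaluate, train

logger = logging.getLogger("thyfuse")

__all__ = ["generate_run", "load_partitions", "train_and_evaluate",
           "run_experiment", "run_ablation"]


def generate_run(config: RunConfig, out_dir=None):
    """Generate the phantom registry for a run, split it 6:2:2, and (when
    ``out_dir`` is given) write the PNG dataset + manifest."""
    data_seed = derive_seed(config.seed, "data")
    registry = generate_dataset(config.n_benign, config.n_malignant,
                                config.informativeness, seed=data_seed)
    registry = stratified_split(registry, seed=derive_seed(config.seed, "split"))
    if out_dir is not None:
        manifest = write_dataset(registry, out_dir)
        logger.info("wrote dataset manifest %s", manifest)
    return registry


def load_partitions(config: RunConfig):
    """Partitions either from an existing PNG manifest or rendered in memory."""
    if config.manifest:
        return load_manifest_partitions(config.manifest, config.image_size)
    registry = generate_run(config)
    return render_partitions(registry, config.image_size)


def train_and_evaluate(config: RunConfig, variant: str | None = None,
                       parts=None, out_dir: Path | None = None):
    """Build, train, and test one variant; optionally write its artifacts.

    Returns (metrics, history, extras).  If a checkpoint for the variant
    already exists under ``out_dir`` the training phase is resumed from it
    (skipped) and only evaluation runs.
    """
    if parts is None:
        parts = load_partitions(config)
    variant = variant or config.model.variant
    from dataclasses import replace
    model_cfg = replace(config.model, variant=variant)
    model_cfg.validate()
    ckpt_path = (out_dir / f"{variant}.checkpoint.npz") if out_dir else None

    if ckpt_path is not None and ckpt_path.exists():
        logger.info("resuming %s from checkpoint %s", variant, ckpt_path)
        model = load_checkpoint(ckpt_path)
        import json
        import numpy as np
        with np.load(ckpt_path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
        model.normalizer = Normalizer.from_dict(meta["normalizer"])
        history = []
    else:
        model = build_variant(model_cfg, seed=derive_seed(config.seed, "init"))
        model, history = train(model, parts["train"], parts["val"], config.train)
        if ckpt_path is not None:
            _save_with_normalizer(model, ckpt_path, config.seed)
    metrics, records, extras = evaluate(model, parts["test"])
    if out_dir is not None:
        _write_records(out_dir / f"{variant}.predictions.tsv", records)
    return metrics, history, extras


def _save_with_normalizer(model, path, seed):
    import json

    import numpy as np
    meta = json.dumps({"config": model.config.to_dict(), "variant": model.variant,
                       "seed": derive_seed(seed, "init"),
                       "normalizer": model.normalizer.to_dict()})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def _write_records(path, records):
    with open(path, "w") as fh:
        fh.write("case_id\tprob_benign\tprob_malignant\tpredicted\ttrue\n")
        for r in records:
            fh.write(f"{r.case_id}\t{r.prob_benign:.6f}\t{r.prob_malignant:.6f}"
                     f"\t{r.predicted_label}\t{r.true_label}\n")


def run_experiment(config_path) -> Path:
    """Full pipeline for one config: dataset -> train -> evaluate -> report.

    Writes, under ``output_dir``: the resolved config echo, the trained
    checkpoint, per-case predictions, a metrics table and a JSON run
    report.  Returns the output directory.
    """
    config = load_run_config(config_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out / "config_resolved.yaml")
    parts = load_partitions(config)
    metrics, history, extras = train_and_evaluate(config, parts=parts, out_dir=out)
    write_metrics_table(out / "metrics.tsv", [(config.model.variant, metrics)])
    write_run_report(out / "report.json", config, history, metrics, extras)
    logger.info("run complete: %s", out / "report.json")
    return out


def run_ablation(config_path, variants: list[str]) -> Path:
    """Train the named variants on one shared dataset and render the
    comparison table (rows = variants, columns = the six metrics)."""
    config = load_run_config(config_path)
    for v in variants:
        if v not in VARIANTS:
            raise ConfigError(f"unknown variant {v!r}; one of {VARIANTS}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out / "config_resolved.yaml")
    parts = load_partitions(config)
    rows = []
    for v in variants:
        metrics, _, extras = train_and_evaluate(config, variant=v, parts=parts,
                                                out_dir=out)
        logger.info("variant %s: f1 %.4f %s", v, metrics.f1, extras)
        rows.append((v, metrics))
    write_metrics_table(out / "ablation.tsv", rows)
    return out
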