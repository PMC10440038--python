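"""Configuration, image, manifest and report I/O.

The run configuration is a single YAML file with nested blocks
``{data, encoder, fusion, model_variant, train, output_dir, seed}``.
Defaults are applied on load, and the fully resolved configuration is
echoed next to every run's outputs so a run can be reproduced from its
own artifacts.  Dataset interchange is 8-bit PNG plus a tab-separated
manifest (case_id, label, partition, us_path, irt_path,
informative_modalities).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .config import ModelConfig, TrainConfig, config_from_dict
from .data import ArrayDataset, prepare_pair
from .errors import ConfigError
from .synthetic import DatasetRegistry, synthesize_irt_image, synthesize_us_image

__all__ = ["RunConfig", "load_run_config", "derive_seed", "load_image_pair",
           "write_dataset", "read_manifest", "load_manifest_partitions",
           "write_metrics_table", "write_run_report"]


def derive_seed(seed: int, name: str) -> int:
    """Named sub-seed (data/init/shuffle) derived from the top-level seed."""
    return int(np.random.SeedSequence([seed, zlib.crc32(name.encode())])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Fully resolved experiment configuration."""

    seed: int
    output_dir: str
    n_benign: int
    n_malignant: int
    informativeness: tuple[float, float, float]
    image_size: int
    manifest: str | None
    model: ModelConfig
    train: TrainConfig

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "data": {
                "n_benign": self.n_benign,
                "n_malignant": self.n_malignant,
                "informativeness": list(self.informativeness),
                "image_size": self.image_size,
                "manifest": self.manifest,
            },
            "encoder": self.model.to_dict()["encoder"],
            "fusion": self.model.to_dict()["fusion"],
            "model_variant": self.model.variant,
            "adapter_hidden": self.model.adapter_hidden,
            "train": self.train.to_dict(),
        }

    def echo(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _require(mapping: dict, key: str, path: str):
    if key not in mapping or mapping[key] is None:
        raise ConfigError(f"missing required config key: {path}")
    return mapping[key]


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    seed = int(_require(raw, "seed", "seed"))
    output_dir = str(_require(raw, "output_dir", "output_dir"))
    data = raw.get("data", {})
    n_benign = int(_require(data, "n_benign", "data.n_benign"))
    n_malignant = int(_require(data, "n_malignant", "data.n_malignant"))
    informativeness = tuple(data.get("informativeness", (0.0, 0.0, 1.0)))
    model = config_from_dict({
        "encoder": raw.get("encoder", {}),
        "fusion": raw.get("fusion", {}),
        "variant": raw.get("model_variant", "ammh"),
        "adapter_hidden": raw.get("adapter_hidden", 256),
    })
    image_size = int(data.get("image_size", model.encoder.input_size))
    if image_size != model.encoder.input_size:
        raise ConfigError(
            f"data.image_size ({image_size}) must equal encoder.input_size "
            f"({model.encoder.input_size})"
        )
    tr = raw.get("train", {})
    train = TrainConfig(
        batch_size=int(tr.get("batch_size", 32)),
        epochs=int(tr.get("epochs", 200)),
        lr_init=float(tr.get("lr_init", 1e-3)),
        lr_min=float(tr.get("lr_min", 1e-4)),
        schedule=tr.get("schedule", "cosine"),
        betas=tuple(tr.get("betas", (0.9, 0.999))),
        weight_decay=float(tr.get("weight_decay", 5e-4)),
        seed=derive_seed(seed, "shuffle"),
    )
    train.validate()
    return RunConfig(seed=seed, output_dir=output_dir, n_benign=n_benign,
                     n_malignant=n_malignant, informativeness=informativeness,
                     image_size=image_size, manifest=data.get("manifest"),
                     model=model, train=train)


# -------------------------------------------------------------------- images

def load_image_pair(us_path, irt_path, size: int = 224):
    """Load a US/IRT PNG pair and preprocess to two 3 x size x size float
    tensors in [0, 1] (bilinear resize; grayscale US replicated to 3
    channels)."""
    arrays = []
    for p, mode in ((us_path, "L"), (irt_path, "RGB")):
        try:
            with Image.open(p) as img:
                arrays.append(np.asarray(img.convert(mode), dtype=np.float32) / 255.0)
        except OSError as exc:
            raise IOError(f"cannot read image file {p}: {exc}") from exc
    us, irt = arrays
    if irt.ndim != 3 or irt.shape[2] != 3:
        raise IOError(f"expected a 3-channel image at {irt_path}")
    return prepare_pair(us, irt, size)


def write_dataset(registry: DatasetRegistry, out_dir) -> Path:
    """Render a registry to 8-bit PNGs plus a tab-separated manifest;
    returns the manifest path."""
    out = Path(out_dir)
    (out / "us").mkdir(parents=True, exist_ok=True)
    (out / "irt").mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in registry.cases:
        us = (np.clip(synthesize_us_image(spec), 0, 1) * 255).astype(np.uint8)
        irt = (np.clip(synthesize_irt_image(spec), 0, 1) * 255).astype(np.uint8)
        us_path = f"us/{spec.case_id}.png"
        irt_path = f"irt/{spec.case_id}.png"
        Image.fromarray(us, mode="L").save(out / us_path)
        Image.fromarray(irt, mode="RGB").save(out / irt_path)
        rows.append((spec.case_id, spec.label,
                     registry.partitions.get(spec.case_id, ""),
                     us_path, irt_path, "+".join(spec.informative)))
    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("case_id\tlabel\tpartition\tus_path\tirt_path\tinformative_modalities\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return manifest


def read_manifest(manifest_path) -> list[dict]:
    path = Path(manifest_path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    lines = path.read_text().strip().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def load_manifest_partitions(manifest_path, size: int) -> dict[str, ArrayDataset]:
    """Load a PNG dataset through its manifest into per-partition arrays."""
    rows = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    parts: dict[str, ArrayDataset] = {}
    for tag in ("train", "val", "test"):
        sel = [r for r in rows if r["partition"] == tag]
        us_l, irt_l, labels, ids = [], [], [], []
        for r in sel:
            us3, irt3 = load_image_pair(root / r["us_path"], root / r["irt_path"], size)
            us_l.append(us3)
            irt_l.append(irt3)
            labels.append(1 if r["label"] == "malignant" else 0)
            ids.append(r["case_id"])
        parts[tag] = ArrayDataset(
            case_ids=ids,
            us=np.stack(us_l) if us_l else np.zeros((0, 3, size, size), np.float32),
            irt=np.stack(irt_l) if irt_l else np.zeros((0, 3, size, size), np.float32),
            labels=np.asarray(labels, dtype=np.int64),
        )
    return parts


# ------------------------------------------------------------------- reports

def write_metrics_table(path, rows: list[tuple[str, "MetricSet"]]) -> None:
    """Tab-separated table: one row per model, six metric columns."""
    with open(path, "w") as fh:
        fh.write("model\tacc\tsen\tpre\tspe\tf1\tf2\n")
        for name, m in rows:
            fh.write(name + "\t" + "\t".join(
                f"{getattr(m, k):.4f}" for k in ("acc", "sen", "pre", "spe", "f1", "f2")
            ) + "\n")


def write_run_report(path, config: RunConfig, history: list[dict],
                     metrics, extras: dict) -> None:
    """Structured JSON run report with stable key order and fixed float
    formatting (byte-identical across reruns of the same seeded run)."""
    payload = {
        "config": config.to_dict(),
        "history": [
            {
                "epoch": h["epoch"],
                "lr": f"{h['lr']:.8f}",
                "train_loss": f"{h['train_loss']:.6f}",
                "val_loss": f"{h['val_loss']:.6f}",
                "val_f1": f"{h['val_metrics'].f1:.6f}",
            }
            for h in history
        ],
        "test_metrics": {k: f"{v:.6f}" for k, v in metrics.as_dict().items()},
        "extras": {k: (({kk: f"{vv:.6f}" for kk, vv in v.items()})
                       if isinstance(v, dict) else v)
                   for k, v in extras.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
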