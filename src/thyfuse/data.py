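"""In-memory dataset preparation: rendering phantom registries to model-ready
arrays and bilinear resizing to the network input size."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .synthetic import CaseSpec, DatasetRegistry, synthesize_irt_image, synthesize_us_image

__all__ = ["ArrayDataset", "resize_float", "prepare_pair", "render_cases", "render_partitions"]


def resize_float(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2-D float image to size x size (float32)."""
    pil = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    return np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float32)


def prepare_pair(us_image: np.ndarray, irt_image: np.ndarray,
                 size: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize one US (HxW) / IRT (HxWx3) pair to two 3 x size x size tensors
    in [0, 1]; the grayscale US frame is replicated to 3 channels."""
    us = resize_float(us_image, size)
    us3 = np.stack([us, us, us], axis=0)
    irt3 = np.stack([resize_float(irt_image[..., c], size) for c in range(3)], axis=0)
    return us3, irt3


@dataclass
class ArrayDataset:
    """Model-ready arrays for one partition: values in [0, 1] before
    normalization; labels are 0 = benign, 1 = malignant."""

    case_ids: list[str]
    us: np.ndarray      # (N, 3, S, S)
    irt: np.ndarray     # (N, 3, S, S)
    labels: np.ndarray  # (N,) int64

    def __len__(self) -> int:
        return len(self.case_ids)


def render_cases(cases: list[CaseSpec], size: int) -> ArrayDataset:
    """Render and resize a list of case specs (deterministic per case via
    each spec's noise seed)."""
    us_list, irt_list, labels, ids = [], [], [], []
    for spec in cases:
        us3, irt3 = prepare_pair(synthesize_us_image(spec),
                                 synthesize_irt_image(spec), size)
        us_list.append(us3)
        irt_list.append(irt3)
        labels.append(1 if spec.label == "malignant" else 0)
        ids.append(spec.case_id)
    return ArrayDataset(
        case_ids=ids,
        us=np.stack(us_list).astype(np.float32),
        irt=np.stack(irt_list).astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
    )


def render_partitions(registry: DatasetRegistry, size: int) -> dict[str, ArrayDataset]:
    """Render the train/val/test partitions of a split registry."""
    return {tag: render_cases(registry.subset(tag), size)
            for tag in ("train", "val", "test")}
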