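"""Dataset serialization, configuration files and reproducibility plumbing.

Coordinate convention (repo-wide): 0-based, upper-left origin, boxes as
``(x, y, w, h)`` with positive extents over half-open pixel intervals.
Annotations live in a single versioned JSON file per dataset; frames are
PNG by default with BMP supported.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .head import BoundingBox
from .records import AnnotatedImage

__all__ = [
    "ANNOTATION_SCHEMA_VERSION",
    "write_dataset",
    "read_dataset",
    "load_yaml_config",
    "config_hash",
]

ANNOTATION_SCHEMA_VERSION = 1


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _frame_record(frame: AnnotatedImage, image_path: str) -> dict:
    return {
        "image_path": image_path,
        "patient_id": frame.patient_id,
        "modality": frame.modality,
        "cleanliness": frame.cleanliness,
        "label": frame.label,
        "boxes": [{"x": b.x, "y": b.y, "w": b.w, "h": b.h} for b in frame.boxes],
    }


def write_dataset(frames: list[AnnotatedImage], out_dir: str | Path,
                  image_format: str = "png", seed: int | None = None,
                  config: dict | None = None) -> Path:
    """Write frames + one annotation JSON + a manifest; returns the directory."""
    if image_format not in ("png", "bmp"):
        raise ValueError(f"unsupported image format {image_format!r}")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    records = []
    for i, frame in enumerate(frames):
        name = f"images/frame{i:06d}.{image_format}"
        iio.imwrite(out / name, (frame.pixels * 255).round().astype(np.uint8))
        records.append(_frame_record(frame, name))
    annotations = {"schema_version": ANNOTATION_SCHEMA_VERSION, "images": records}
    (out / "annotations.json").write_text(json.dumps(annotations, indent=1))
    manifest = {
        "n_images": len(frames),
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config or {}),
        "patient_ids": sorted({f.patient_id for f in frames}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(dataset_dir: str | Path) -> list[AnnotatedImage]:
    root = Path(dataset_dir)
    annotations = json.loads((root / "annotations.json").read_text())
    if annotations.get("schema_version") != ANNOTATION_SCHEMA_VERSION:
        raise ValueError("unknown annotation schema version")
    frames = []
    for rec in annotations["images"]:
        pixels = iio.imread(root / rec["image_path"]).astype(np.float32) / 255.0
        boxes = [BoundingBox(b["x"], b["y"], b["w"], b["h"]) for b in rec["boxes"]]
        frames.append(AnnotatedImage(
            pixels=pixels, boxes=boxes, patient_id=rec["patient_id"],
            modality=rec["modality"], cleanliness=rec["cleanliness"],
            frame_id=rec["image_path"],
        ))
    return frames


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
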