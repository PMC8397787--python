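"""Shared plumbing: manifest CSV I/O, image files, config and report files.

Manifests are plain CSV with the header ``path,label,patient_id,protocol,
split`` (labels stored as canonical lowercase tokens, accepted
case-insensitively on read).  Configs are YAML; evaluation reports are JSON
with stable key order so that two runs with the same seed and config produce
byte-identical files apart from the timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .samples import CLASS_NAMES, DatasetManifest, ImageSample, canonical_label

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_image",
    "write_image",
    "write_report",
    "read_report",
    "load_config",
    "dump_config",
]

_REQUIRED_COLUMNS = ("path", "label", "patient_id")


def read_image(path: str | Path) -> np.ndarray:
    """Load an image file as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_manifest(
    path: str | Path, load_pixels: bool = False, check_files: bool = True
) -> DatasetManifest:
    """Read a manifest CSV, validating labels and referenced image files.

    Unknown labels and missing image files are rejected with the offending
    row named.  ``load_pixels`` additionally loads every image into memory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    samples: list[ImageSample] = []
    split: dict[str, str] = {}
    for i, row in df.iterrows():
        try:
            label = canonical_label(row["label"])
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        img_path = row["path"]
        pixels = None
        if img_path:
            full = path.parent / img_path if not Path(img_path).is_absolute() else Path(img_path)
            if check_files and not full.exists():
                raise FileNotFoundError(f"{path} row {i}: image file not found: {full}")
            if load_pixels:
                pixels = read_image(full)
            img_path = str(full)
        source_id = row.get("source_id", "") or f"{path.stem}_{i:05d}"
        sample = ImageSample(
            label=label,
            patient_id=row["patient_id"],
            source_id=source_id,
            protocol=row.get("protocol", "") or "centered",
            pixels=pixels,
            path=img_path or None,
        )
        samples.append(sample)
        side = (row.get("split", "") or "").strip().lower()
        if side:
            if side not in ("train", "test"):
                raise ValueError(f"{path} row {i}: split must be train/test, got {side!r}")
            split[sample.source_id] = side
    manifest = DatasetManifest(samples=samples, split=split)
    if split:
        manifest.validate_split()
    return manifest


def write_manifest(
    manifest: DatasetManifest, path: str | Path, image_dir: str | Path | None = None
) -> None:
    """Write a manifest CSV; optionally save each sample's pixels as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in manifest.samples:
        img_path = s.path or ""
        if image_dir is not None and s.pixels is not None:
            img_path = str(Path(image_dir) / f"{s.source_id}.png")
            write_image(s.pixels, path.parent / img_path)
        rows.append(
            {
                "path": img_path,
                "label": s.label,
                "patient_id": s.patient_id,
                "source_id": s.source_id,
                "protocol": s.protocol,
                "split": manifest.split.get(s.source_id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(
    results: dict, path: str | Path, config: dict | None = None, seed: int | None = None
) -> None:
    """Write a JSON report with stable key order plus provenance fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(results)
    payload["_provenance"] = {
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
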