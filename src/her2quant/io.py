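"""Checkpoint and provenance I/O.

A model checkpoint is an ``.npz`` of the state dict plus a JSON sidecar
(``<path>.json``) recording the architecture configuration, the class order
and any extra metadata (seed, training config), so a checkpoint is
self-describing and reloadable without the originating script.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np

from .backbone import TileClassifier, build_model
from .config import TILE_CLASSES, ModelConfig


def save_checkpoint(model: TileClassifier, path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "model_config": model.config.to_dict(),
        "class_order": list(TILE_CLASSES),
        "dtype": str(model.head.weight.data.dtype),
    }
    if extra:
        sidecar.update(extra)
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def load_checkpoint(path: str | Path) -> TileClassifier:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with open(f"{path}.json") as fh:
        sidecar = json.load(fh)
    config = ModelConfig.from_dict(sidecar["model_config"])
    model = build_model(config, seed=0, dtype=np.dtype(sidecar.get("dtype", "float32")))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir: str | Path, command: str, params: dict,
                     inputs: list[str | Path] | None = None) -> Path:
    """Record how an artifact was produced (config hash, seeds, versions)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()}
    record = {
        "command": command,
        "params": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "her2quant": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "input_checksums": {
            str(p): file_sha256(p) for p in (inputs or []) if Path(p).is_file()
        },
    }
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    return path
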