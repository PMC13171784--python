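"""Layered YAML configuration, seed fan-out and run manifests.

Defaults equal the published training hyperparameters (250 epochs, batch 8,
Adam with weight decay 2·10⁻⁴, cosine annealing from 5·10⁻⁴, early-stop
patience 20, boosting every 15 epochs with factors 1.3/1.2/1.1 at Dice
thresholds 0.3/0.5/0.7).  A single global seed fans out to per-stage seeds
by stable hashing, so every pipeline stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "pixel_size_um": 0.227,
    "vessel_patch_px": 1024,
    "lobule_patch_px": 2048,
    "test_frac": 0.10,
    "k_folds": 5,
    "epochs": 250,
    "batch_size": 8,
    "eta_max": 5e-4,
    "eta_min": 0.0,
    "weight_decay": 2e-4,
    "patience": 20,
    "boost_period_epochs": 15,
    "boost_thresholds": [0.3, 0.5, 0.7],
    "boost_factors": [1.3, 1.2, 1.1],
    "boost_weight_cap": 10.0,
    "vessel_loss_weights": [0.2, 0.6, 0.2],
    "lobule_loss_weights": [0.5, 0.5, 0.0],
    "inference_overlap": 0.5,
    "septa_close_radius_um": 15.0,
    "seed": 0,
}


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Defaults, overlaid with a YAML file, overlaid with CLI overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def write_manifest(out_dir: str | Path, stage: str, cfg: dict[str, Any],
                   inputs: dict[str, str] | None = None) -> Path:
    """Snapshot the effective config, seed and inputs of one run to JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.items()},
        "inputs": inputs or {},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
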