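"""Serialization of model bundles, reports and run configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .cv import CVConfig, default_rf_grid

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run-wide configuration; embedded (as a hash) in every output artifact."""

    smiles_col: str = "smiles"
    variance_threshold: float = 0.05
    correlation_threshold: float = 0.95
    mw_k: float = 1.5
    ad_threshold: float = 0.25
    base_seed: int = 0
    n_repeats: int = 5
    n_outer_folds: int = 5
    n_inner_folds: int = 4
    scale_within_folds: bool = False
    hyper_grid: list = field(default_factory=default_rf_grid)

    def cv_config(self) -> CVConfig:
        return CVConfig(
            n_repeats=self.n_repeats,
            n_outer_folds=self.n_outer_folds,
            n_inner_folds=self.n_inner_folds,
            hyper_grid=self.hyper_grid,
            base_seed=self.base_seed,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json_report(payload: dict, path: str | Path, config: PipelineConfig | None = None):
    payload = dict(payload)
    payload["schema_version"] = SCHEMA_VERSION
    if config is not None:
        payload["config_hash"] = config.digest()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyEncoder)


def save_bundle(obj, path: str | Path):
    """Persist a model archive (ModelBundle / AnimalModelSet / HumanModelSet)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"schema_version": SCHEMA_VERSION, "payload": obj}, path)


def load_bundle(path: str | Path):
    try:
        archive = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable model archive {path}: {exc}") from exc
    if not isinstance(archive, dict) or "payload" not in archive:
        raise ValueError(f"not a model archive: {path}")
    if archive.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version mismatch in {path}: "
            f"{archive.get('schema_version')} != {SCHEMA_VERSION}"
        )
    return archive["payload"]
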