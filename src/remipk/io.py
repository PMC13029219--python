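"""File formats and configuration.

Datasets are plain CSV in the event-record dialect (see
:mod:`remipk.dataset`); regimens and run configurations are JSON or YAML
documents validated strictly — unknown keys are rejected by name so that
simulation experiments stay auditable.  Times are stored in minutes;
AUC columns are ng*h/mL.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .dataset import MANDATORY_COLUMNS, PKDataset
from .regimen import Regimen

__all__ = ["read_dataset", "write_dataset", "load_config", "load_regimen", "dump_json"]


def read_dataset(path) -> PKDataset:
    """Read and validate an event-record CSV."""
    df = pd.read_csv(path)
    return PKDataset(df)


def write_dataset(dataset: PKDataset, path) -> None:
    cols = [c for c in MANDATORY_COLUMNS if c in dataset.df.columns]
    cols += [c for c in dataset.df.columns if c not in cols]
    dataset.df[cols].to_csv(path, index=False)


def load_config(path, allowed_keys=None) -> dict:
    """Load a JSON/YAML config; reject unknown keys by name when
    ``allowed_keys`` is given."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return cfg


def load_regimen(path) -> Regimen:
    cfg = load_config(path)
    return Regimen.from_dict(cfg)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    try:
        import numpy as np

        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except Exception:
        pass
    if hasattr(x, "to_dict"):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")
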