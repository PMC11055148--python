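"""File I/O: signal CSVs, configuration, and tidy result tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import GaitSimSpec

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "load_config",
    "DEFAULT_CONFIG",
]


def read_signal_csv(path: str | Path) -> np.ndarray:
    """Read a single-column signal file, tolerating one header line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty signal file")
    try:
        float(lines[0])
    except ValueError:
        lines = lines[1:]
    return np.array([float(ln) for ln in lines])


def write_signal_csv(path: str | Path, values: Sequence[float] | np.ndarray,
                     header: str | None = "angle_deg") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [header] if header else []
    rows += [repr(float(v)) for v in np.asarray(values, dtype=float)]
    path.write_text("\n".join(rows) + "\n")


def write_json(path: str | Path, payload: Any) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def spec_to_dict(spec: GaitSimSpec) -> dict:
    d = asdict(spec)
    d["harmonics"] = list(spec.harmonics)
    return d


#: Baseline run configuration; a YAML config file overrides any subset.
DEFAULT_CONFIG: dict[str, Any] = {
    "outdir": "runs/default",
    "cohort": {"n_subjects": 15, "base_seed": 1},
    "signal": {},              # GaitSimSpec field overrides
    "experiments": [1, 2],
    "models": ["fret", "nnet_static", "nnet_updated", "dnnet_static", "dnnet_updated"],
    "iterations": 10,
    "seed": 1,
    "partition": "quantile",
    "offset": 3,
    "update_epochs": 50,
    "grid": {
        "m": [1, 2, 3, 4, 5],
        "units": [1, 2, 4, 6, 8],
        "layers": [2, 3],
    },
    "fit_max_iter": 200,
}


def load_config(path: str | Path | None, **overrides: Any) -> dict[str, Any]:
    """Merge defaults <- YAML file <- keyword overrides (shallow per key)."""
    cfg: dict[str, Any] = {k: (dict(v) if isinstance(v, dict) else v)
                           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for k, v in loaded.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in overrides.items():
        if v is not None:
            cfg[k] = v
    return cfg


def results_frame(rows: Sequence[dict]) -> pd.DataFrame:
    """Tidy per-window results table shared by the CLI commands."""
    return pd.DataFrame(
        rows,
        columns=["model", "experiment", "subject", "iteration",
                 "window", "nrmse", "elapsed", "skipped"],
    )
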