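"""Result serialization: trajectory/sweep CSVs and JSON config sidecars.

Every CSV written for a run or sweep gets a JSON sidecar recording the fully
resolved configuration (defaults filled), the seed(s), and the package
version, so any output can be regenerated exactly from its sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfigFile, run_from_config

__all__ = [
    "write_trajectory",
    "write_sweep",
    "write_grid_snapshot",
    "sidecar_path",
    "rerun_from_sidecar",
]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".config.json")


def _write_sidecar(csv_path, payload: dict) -> None:
    payload = dict(payload)
    payload["package_version"] = __version__
    sidecar_path(csv_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_trajectory(df: pd.DataFrame, csv_path, config: RunConfigFile) -> None:
    """Write a trajectory CSV plus a sidecar holding the resolved run config."""
    df.to_csv(csv_path, index=False)
    _write_sidecar(
        csv_path,
        {"type": "trajectory", "config": config.model_dump(exclude_none=True)},
    )


def write_sweep(df: pd.DataFrame, csv_path, meta: dict) -> None:
    """Write a tidy sweep table plus a sidecar with the sweep settings.

    ``meta`` should carry the sweep name, master seed, parameter values,
    replicate count, and any game/network settings needed to re-run it.
    """
    df.to_csv(csv_path, index=False)
    _write_sidecar(csv_path, {"type": "sweep", **meta})


def write_grid_snapshot(grid: np.ndarray, path) -> None:
    """Write a side x side matrix of state/strain codes as CSV."""
    np.savetxt(path, np.asarray(grid), fmt="%d", delimiter=",")


def rerun_from_sidecar(sidecar, csv_path) -> pd.DataFrame:
    """Re-execute the run described by a trajectory sidecar.

    Writes the regenerated CSV to ``csv_path`` and returns the table; with an
    unmodified sidecar this reproduces the original CSV byte-for-byte.
    """
    payload = json.loads(Path(sidecar).read_text())
    if payload.get("type") != "trajectory":
        raise ValueError("sidecar does not describe a single trajectory run")
    config = RunConfigFile.model_validate(payload["config"])
    df = run_from_config(config)
    write_trajectory(df, csv_path, config)
    return df
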