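"""Trial serialization: one delimited table per trial plus a dataset manifest.

Trials are written as CSV with columns ``t, emg_raw, activation, lce, vce,
force``; the manifest (JSON or YAML) lists per-trial metadata and file
names.  A thin adapter reads externally recorded tables through a declared
column mapping, so deposited datasets can be used without code changes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Trial

__all__ = [
    "trial_to_frame",
    "frame_to_trial",
    "write_trial",
    "read_trial",
    "save_dataset",
    "load_dataset",
    "read_external_trial",
]

COLUMNS = ("t", "emg_raw", "activation", "lce", "vce", "force")


def trial_to_frame(trial: Trial) -> pd.DataFrame:
    return pd.DataFrame({c: getattr(trial, c) for c in COLUMNS})


def frame_to_trial(df: pd.DataFrame, meta: dict | None = None) -> Trial:
    return Trial(**{c: df[c].to_numpy(dtype=float) for c in COLUMNS}, meta=meta or {})


def write_trial(trial: Trial, path: str | Path) -> None:
    trial_to_frame(trial).to_csv(path, index=False, float_format="%.10g")


def read_trial(path: str | Path, meta: dict | None = None) -> Trial:
    return frame_to_trial(pd.read_csv(path), meta=meta)


def save_dataset(trials: list[Trial], directory: str | Path, fmt: str = "json") -> Path:
    """Write trial tables and a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trial in enumerate(trials):
        name = f"trial_{i:04d}.csv"
        write_trial(trial, directory / name)
        entries.append({"file": name, "meta": trial.meta})
    manifest = {"n_trials": len(trials), "trials": entries}
    if fmt == "yaml":
        path = directory / "manifest.yaml"
        path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    else:
        path = directory / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
    return path


def load_dataset(manifest_path: str | Path) -> list[Trial]:
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = (
        yaml.safe_load(text) if manifest_path.suffix in (".yaml", ".yml") else json.loads(text)
    )
    trials = []
    for entry in manifest["trials"]:
        trials.append(read_trial(manifest_path.parent / entry["file"], meta=entry.get("meta", {})))
    return trials


def read_external_trial(
    path: str | Path,
    column_map: dict,
    meta: dict | None = None,
    fs: float | None = None,
    sep: str = ",",
) -> Trial:
    """Read an externally recorded trial table via a declared column mapping.

    ``column_map`` maps our canonical names (``t``, ``emg_raw``, ``lce``,
    ``vce``, ``force``, optionally ``activation``) to the file's column
    names.  When ``t`` is absent, ``fs`` must be given and a uniform time
    base is constructed.  Missing ``activation`` is filled with zeros (to be
    recomputed from ``emg_raw`` by the preprocessing chain); missing ``vce``
    is left to the caller to recompute from ``lce``.
    """
    df = pd.read_csv(path, sep=sep)
    data: dict[str, np.ndarray] = {}
    for canonical, source in column_map.items():
        if canonical not in COLUMNS:
            raise ValueError(f"unknown canonical column {canonical!r}")
        data[canonical] = df[source].to_numpy(dtype=float)
    n = len(df)
    if "t" not in data:
        if fs is None:
            raise ValueError("fs is required when the table has no time column")
        data["t"] = np.arange(n) / fs
    for optional in ("emg_raw", "activation", "vce", "force"):
        data.setdefault(optional, np.zeros(n))
    if "lce" not in data:
        raise ValueError("column_map must provide lce")
    return Trial(**data, meta=meta or {})
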