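"""Plain-text readers and writers for trial traces, tables, and run configs.

All artifacts are UTF-8 delimited text with decimal points so every output
round-trips through its reader without loss: trial traces as
``time_s,fz_left_n,fz_right_n`` CSV, tables as CSV with documented headers,
and run configurations as YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Trial
from .grf import ForceTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_trials",
    "read_trials",
    "write_table",
    "read_table",
    "load_config",
    "dump_config",
    "config_hash",
    "InputFileError",
]

TRACE_HEADER = "time_s,fz_left_n,fz_right_n"
FLOAT_FMT = "%.6f"


class InputFileError(ValueError):
    """A data file is missing, malformed, or inconsistent."""


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    data = np.column_stack([trace.time_s, trace.fz_left_n, trace.fz_right_n])
    np.savetxt(path, data, fmt=FLOAT_FMT, delimiter=",",
               header=TRACE_HEADER, comments="")


def read_trace(path: str | Path) -> ForceTrace:
    path = Path(path)
    if not path.is_file():
        raise InputFileError(f"trial file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise InputFileError(f"cannot parse trial file {path}: {err}") from err
    missing = {"time_s", "fz_left_n", "fz_right_n"} - set(df.columns)
    if missing:
        raise InputFileError(
            f"trial file {path} lacks columns {sorted(missing)} (line 1)"
        )
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise InputFileError(f"non-numeric or missing value in {path}, line {line}")
    try:
        return ForceTrace(
            time_s=df["time_s"].to_numpy(),
            fz_left_n=df["fz_left_n"].to_numpy(),
            fz_right_n=df["fz_right_n"].to_numpy(),
        )
    except ValueError as err:
        raise InputFileError(f"invalid trace in {path}: {err}") from err


def trial_filename(trial: Trial) -> str:
    return (
        f"{trial.subject_id}_{trial.clothing}_{trial.height_m:g}m_"
        f"t{trial.trial}.csv"
    )


def write_trials(trials: list[Trial], trials_dir: str | Path) -> pd.DataFrame:
    """Write every trial trace plus an ``index.csv`` mapping files to design
    coordinates; returns the index table."""
    trials_dir = Path(trials_dir)
    trials_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        fname = trial_filename(tr)
        write_trace(tr.trace, trials_dir / fname)
        rows.append(
            dict(
                filename=fname,
                subject_id=tr.subject_id,
                age_group=tr.age_group,
                clothing=tr.clothing,
                height_m=tr.height_m,
                trial=tr.trial,
            )
        )
    index = pd.DataFrame(rows)
    index.to_csv(trials_dir / "index.csv", index=False)
    return index


def read_trials(trials_dir: str | Path) -> list[Trial]:
    """Load all trials listed in ``<trials_dir>/index.csv``."""
    trials_dir = Path(trials_dir)
    index_path = trials_dir / "index.csv"
    if not index_path.is_file():
        raise InputFileError(f"trial index not found: {index_path}")
    index = pd.read_csv(index_path)
    needed = {"filename", "subject_id", "age_group", "clothing", "height_m", "trial"}
    missing = needed - set(index.columns)
    if missing:
        raise InputFileError(f"{index_path} lacks columns {sorted(missing)}")
    trials = []
    for row in index.itertuples(index=False):
        trace = read_trace(trials_dir / row.filename)
        trials.append(
            Trial(
                subject_id=str(row.subject_id),
                age_group=str(row.age_group),
                clothing=str(row.clothing),
                height_m=float(row.height_m),
                trial=int(row.trial),
                trace=trace,
            )
        )
    return trials


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    # default float formatting is the shortest exact repr, so every table
    # round-trips through read_table without loss
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputFileError(f"table not found: {path}")
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.is_file():
        raise InputFileError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise InputFileError(f"cannot parse config {path}: {err}") from err
    if not isinstance(cfg, dict):
        raise InputFileError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration mapping (for the run manifest)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
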