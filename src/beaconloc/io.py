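"""Delimited-text readers and writers for every stream the pipeline touches.

All files are plain CSV with ISO-8601 UTC timestamps; epochs are half-open
``[t, t + interval)`` on the grid anchored at the stream's first timestamp
(or an explicit ``t0``).  Schemas:

* RSSI:          ``timestamp, receiver_id, beacon_id, rssi_dbm``
* steps:         ``timestamp, receiver_id, steps`` (one row per 10-s epoch)
* acceleration:  ``timestamp, ax, ay, az`` (100 Hz, g-units)
* ground truth:  ``timestamp, area_id``
* trace output:  ``timestamp, receiver_id, map_area_raw, map_area_smoothed,
  exception_flags`` plus optional wide ``prob_<area>`` columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import GroundTruthTrace
from .filtering import LocalizationTrace
from .measurement import RssiSample
from .motion import StepEpoch

logger = logging.getLogger(__name__)

DEFAULT_T0 = pd.Timestamp("2018-01-01T00:00:00Z")


class SchemaError(ValueError):
    """A stream file does not match its documented schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_timestamps(df: pd.DataFrame, path) -> pd.Series:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise SchemaError(f"{path}: malformed timestamp at line(s) {lines[:10]}")
    return ts


def _epoch_index(ts: pd.Series, epoch_s: float, t0: pd.Timestamp | None) -> np.ndarray:
    if t0 is None:
        t0 = ts.min()
    rel = (ts - t0).dt.total_seconds().to_numpy()
    return np.floor(rel / epoch_s).astype(int)


def _timestamp_col(t_index, epoch_s: float, t0: pd.Timestamp) -> pd.Series:
    return pd.Series(
        [t0 + pd.Timedelta(seconds=float(k) * epoch_s) for k in t_index]
    ).dt.strftime("%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------- RSSI

def write_rssi_csv(
    samples: Sequence[RssiSample], path, epoch_s: float = 10.0,
    t0: pd.Timestamp = DEFAULT_T0,
) -> None:
    df = pd.DataFrame(
        {
            "timestamp": _timestamp_col([s.t_index for s in samples], epoch_s, t0),
            "receiver_id": [s.receiver_id for s in samples],
            "beacon_id": [s.beacon_id for s in samples],
            "rssi_dbm": [s.rssi for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_rssi_csv(
    path, epoch_s: float = 10.0, t0: pd.Timestamp | None = None
) -> dict[str, list[RssiSample]]:
    """Per-receiver RSSI streams, epoch-binned on the configured interval."""
    df = pd.read_csv(path)
    streams: dict[str, list[RssiSample]] = {}
    if df.empty:
        logger.warning("%s: empty RSSI file", path)
        return streams
    _check_columns(df, ["timestamp", "receiver_id", "beacon_id", "rssi_dbm"], path)
    ts = _parse_timestamps(df, path)
    idx = _epoch_index(ts, epoch_s, t0)
    for k, rec, bid, rssi in zip(
        idx, df["receiver_id"], df["beacon_id"], df["rssi_dbm"]
    ):
        streams.setdefault(str(rec), []).append(
            RssiSample(t_index=int(k), receiver_id=str(rec),
                       beacon_id=str(bid), rssi=float(rssi))
        )
    return streams


# ---------------------------------------------------------------- steps

def write_steps_csv(
    steps: Sequence[StepEpoch], path, receiver_id: str = "R1",
    epoch_s: float = 10.0, t0: pd.Timestamp = DEFAULT_T0,
) -> None:
    df = pd.DataFrame(
        {
            "timestamp": _timestamp_col([s.t_index for s in steps], epoch_s, t0),
            "receiver_id": receiver_id,
            "steps": [s.steps for s in steps],
        }
    )
    df.to_csv(path, index=False)


def read_steps_csv(
    path, epoch_s: float = 10.0, t0: pd.Timestamp | None = None
) -> dict[str, list[StepEpoch]]:
    df = pd.read_csv(path)
    streams: dict[str, list[StepEpoch]] = {}
    if df.empty:
        logger.warning("%s: empty step-count file", path)
        return streams
    _check_columns(df, ["timestamp", "receiver_id", "steps"], path)
    ts = _parse_timestamps(df, path)
    idx = _epoch_index(ts, epoch_s, t0)
    for k, rec, n in zip(idx, df["receiver_id"], df["steps"]):
        streams.setdefault(str(rec), []).append(StepEpoch(t_index=int(k), steps=int(n)))
    return streams


# ---------------------------------------------------------------- acceleration

def write_accel_csv(accel: Mapping[str, np.ndarray], path,
                    t0: pd.Timestamp = DEFAULT_T0) -> None:
    t = np.asarray(accel["t"], dtype=float)
    ts = (t0 + pd.to_timedelta(t, unit="s")).strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    pd.DataFrame(
        {"timestamp": ts, "ax": accel["ax"], "ay": accel["ay"], "az": accel["az"]}
    ).to_csv(path, index=False)


def read_accel_csv(path, t0: pd.Timestamp | None = None) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty acceleration file", path)
        return {k: np.empty(0) for k in ("t", "ax", "ay", "az")}
    _check_columns(df, ["timestamp", "ax", "ay", "az"], path)
    ts = _parse_timestamps(df, path)
    if t0 is None:
        t0 = ts.min()
    return {
        "t": (ts - t0).dt.total_seconds().to_numpy(),
        "ax": df["ax"].to_numpy(float),
        "ay": df["ay"].to_numpy(float),
        "az": df["az"].to_numpy(float),
    }


# ---------------------------------------------------------------- ground truth

def write_truth_csv(truth: GroundTruthTrace, path,
                    t0: pd.Timestamp = DEFAULT_T0) -> None:
    df = pd.DataFrame(
        {
            "timestamp": _timestamp_col(range(truth.n_epochs), truth.epoch_s, t0),
            "area_id": truth.area_ids,
        }
    )
    df.to_csv(path, index=False)


def read_truth_csv(
    path, epoch_s: float = 10.0, t0: pd.Timestamp | None = None
) -> GroundTruthTrace:
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty ground-truth file", path)
        return GroundTruthTrace(area_ids=[], epoch_s=epoch_s)
    _check_columns(df, ["timestamp", "area_id"], path)
    _parse_timestamps(df, path)
    return GroundTruthTrace(area_ids=[str(a) for a in df["area_id"]], epoch_s=epoch_s)


# ---------------------------------------------------------------- trace

def write_trace_csv(
    trace: LocalizationTrace, path, epoch_s: float = 10.0,
    t0: pd.Timestamp = DEFAULT_T0, include_probs: bool = False,
) -> None:
    df = trace.to_dataframe(include_probs=include_probs)
    df.insert(0, "timestamp", _timestamp_col(df.pop("t_index"), epoch_s, t0))
    df.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(
        df, ["timestamp", "receiver_id", "map_area_raw", "map_area_smoothed"], path
    )
    df["exception_flags"] = df.get("exception_flags", pd.Series(dtype=str)).fillna("")
    return df


def read_streams(
    rssi_path,
    steps_path=None,
    truth_path=None,
    epoch_s: float = 10.0,
) -> dict:
    """Read RSSI/steps/truth files onto one shared epoch grid.

    The grid is anchored at the earliest timestamp across all files, so a
    dropout at the start of one stream cannot shift it against the others.
    Returns ``{"rssi": {receiver: [...]}, "steps": {receiver: [...]},
    "truth": GroundTruthTrace | None, "t0": Timestamp}``.
    """
    t0s = []
    for p in (rssi_path, steps_path, truth_path):
        if p is None:
            continue
        df = pd.read_csv(p)
        if df.empty:
            continue
        if "timestamp" not in df.columns:
            raise SchemaError(f"{p}: missing required column(s) ['timestamp']")
        t0s.append(_parse_timestamps(df, p).min())
    t0 = min(t0s) if t0s else DEFAULT_T0
    return {
        "rssi": read_rssi_csv(rssi_path, epoch_s, t0),
        "steps": read_steps_csv(steps_path, epoch_s, t0) if steps_path else {},
        "truth": read_truth_csv(truth_path, epoch_s, t0) if truth_path else None,
        "t0": t0,
    }


def write_trial(trial, out_dir, t0: pd.Timestamp = DEFAULT_T0) -> dict[str, Path]:
    """Write a SyntheticTrial's four streams plus its config as JSON."""
    import dataclasses
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epoch_s = trial.config.epoch_s
    paths = {
        "rssi": out / "rssi.csv",
        "steps": out / "steps.csv",
        "accel": out / "accel.csv",
        "truth": out / "truth.csv",
        "config": out / "config.json",
    }
    write_rssi_csv(trial.rssi_samples, paths["rssi"], epoch_s, t0)
    write_steps_csv(trial.steps, paths["steps"], "R1", epoch_s, t0)
    write_accel_csv(trial.accel, paths["accel"], t0)
    write_truth_csv(trial.truth, paths["truth"], t0)
    cfg = dataclasses.asdict(trial.config)
    paths["config"].write_text(json.dumps(cfg, indent=2, default=str))
    return paths
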