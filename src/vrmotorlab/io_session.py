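"""Readers and writers for the study's external formats.

Three kinds of artefact move in and out of the pipeline:

* **Trajectory CSV** -- headset controller exports: comma-separated with a
  header and columns ``t,x,y,z`` (seconds and metres, world frame) sampled
  at a nominal 60 Hz.  Millisecond timestamps are auto-detected (median
  sample interval > 1) and converted.
* **Session logs** -- JSON-lines, one header record followed by one record
  per block, round-tripping :class:`~vrmotorlab.regulator.SessionLog`
  exactly.
* **Outcome tables** -- long-format CSV
  ``participant_id,time_point,outcome_name,value`` with one row per cell;
  missing values stay missing (empty field -> NaN), never zero.

Run configurations are single YAML files (see :func:`load_config`).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, ParameterError
from .regulator import BlockLog, DifficultyState, SessionLog, TrialEvent

PathLike = Union[str, "io.IOBase"]

TIME_POINTS = ("T0", "T1", "T2")
OUTCOME_COLUMNS = ["participant_id", "time_point", "outcome_name", "value"]


# --- trajectories ----------------------------------------------------------

@dataclass
class QualityReport:
    """Preliminary acquisition-quality summary attached to every read."""

    n_samples: int
    duration_s: float
    gap_count: int
    median_dt_s: float


@dataclass
class Trajectory:
    """Time-stamped 3D controller positions for one drawing task.

    ``t`` is seconds since task start (strictly increasing), ``xyz`` an
    (n, 3) array of positions in metres in the headset world frame.
    """

    t: np.ndarray
    xyz: np.ndarray
    nominal_rate: float = 60.0
    task: str = "line"  # line | circle
    hand: str = "dominant"  # dominant | nondominant
    quality: Optional[QualityReport] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise IntegrityError(
                f"shape mismatch: t has {self.t.size} samples, xyz is {self.xyz.shape}"
            )
        if self.t.size < 2:
            raise IntegrityError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise IntegrityError("non-finite timestamp or position")
        if self.t[0] < 0:
            raise IntegrityError("timestamps must be non-negative")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise IntegrityError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
        med = float(np.median(dt))
        if not (0.8 / self.nominal_rate <= med <= 1.2 / self.nominal_rate):
            raise IntegrityError(
                f"median sample interval {med:.4g}s deviates more than 20% "
                f"from 1/{self.nominal_rate:g}s"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _quality(t: np.ndarray, nominal_rate: float) -> QualityReport:
    dt = np.diff(t)
    med = float(np.median(dt))
    gaps = int(np.sum(dt > 1.5 / nominal_rate))
    return QualityReport(
        n_samples=int(t.size),
        duration_s=float(t[-1] - t[0]),
        gap_count=gaps,
        median_dt_s=med,
    )


def read_trajectory(
    source: PathLike,
    nominal_rate: float = 60.0,
    task: str = "line",
    hand: str = "dominant",
) -> Trajectory:
    """Read a controller-export CSV into a validated :class:`Trajectory`.

    Expects header columns ``t,x,y,z`` (``time`` accepted for ``t``).
    Timestamps in milliseconds are detected from the median sample interval
    and converted to seconds.  A :class:`QualityReport` (sample count,
    duration, gap count) is attached, standing in for the study's
    preliminary visual data check.
    """
    df = pd.read_csv(source)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "time" in df.columns and "t" not in df.columns:
        df = df.rename(columns={"time": "t"})
    for col in ("t", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"trajectory CSV is missing column {col!r}")
    if len(df) < 2:
        raise IntegrityError("trajectory has fewer than 2 samples")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise IntegrityError(
            f"non-increasing timestamp at row {int(bad[0]) + 1}"
        )
    if np.median(dt) > 1.0:  # sub-1 Hz in seconds => this is milliseconds
        t = t / 1000.0
    t = t - t[0]
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    traj = Trajectory(
        t=t,
        xyz=xyz,
        nominal_rate=nominal_rate,
        task=task,
        hand=hand,
        quality=_quality(t, nominal_rate),
    )
    return traj


def write_trajectory(traj: Trajectory, dest: PathLike) -> None:
    """Write a trajectory back to the ``t,x,y,z`` CSV dialect."""
    df = pd.DataFrame(
        {"t": traj.t, "x": traj.xyz[:, 0], "y": traj.xyz[:, 1], "z": traj.xyz[:, 2]}
    )
    df.to_csv(dest, index=False)


# --- session logs ----------------------------------------------------------

def _event_to_dict(ev: TrialEvent) -> dict:
    d = {"kind": ev.kind, "location": list(ev.location)}
    if ev.latency is not None:
        d["latency"] = ev.latency
    if ev.distractor_salience != "none":
        d["distractor_salience"] = ev.distractor_salience
    return d


def _event_from_dict(d: dict) -> TrialEvent:
    kind = d.get("kind")
    if kind not in ("hit", "omission", "false_positive"):
        raise FormatError(f"unknown trial event kind {kind!r} in session log")
    return TrialEvent(
        kind=kind,
        location=tuple(d["location"]),
        latency=d.get("latency"),
        distractor_salience=d.get("distractor_salience", "none"),
    )


def _state_to_dict(state: DifficultyState) -> dict:
    return {
        "exposure_level": state.exposure_level,
        "area_level": state.area_level,
        "n_distractors": state.n_distractors,
        "salience_mix": state.salience_mix,
        "cue_mode": state.cue_mode,
        "spawn_bias": state.spawn_bias,
    }


def write_session_log(session: SessionLog, dest: PathLike) -> None:
    """Serialize a session as JSON-lines: a header, then one block per line."""
    if not session.blocks:
        raise IntegrityError("session contains no blocks")
    records = [
        {
            "record": "session",
            "learner_id": session.learner_id,
            "seed": session.seed,
            "n_blocks": len(session.blocks),
        }
    ]
    for block in session.blocks:
        records.append(
            {
                "record": "block",
                "block_index": block.block_index,
                "state": _state_to_dict(block.state_used),
                "trials": [_event_to_dict(ev) for ev in block.trials],
            }
        )
    text = "\n".join(json.dumps(r) for r in records) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def read_session_log(source: PathLike) -> SessionLog:
    """Inverse of :func:`write_session_log`; exact round-trip."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty session log")
    header = json.loads(lines[0])
    if header.get("record") != "session":
        raise FormatError("session log must start with a session header record")
    blocks: List[BlockLog] = []
    for ln in lines[1:]:
        rec = json.loads(ln)
        if rec.get("record") != "block":
            raise FormatError(f"unexpected record type {rec.get('record')!r}")
        state = DifficultyState(**rec["state"])
        trials = tuple(_event_from_dict(d) for d in rec["trials"])
        blocks.append(
            BlockLog(block_index=rec["block_index"], trials=trials, state_used=state)
        )
    if not blocks:
        raise IntegrityError("session log contains no blocks")
    return SessionLog(blocks=blocks, learner_id=header["learner_id"], seed=header["seed"])


# --- outcome tables --------------------------------------------------------

def read_outcome_table(source: PathLike) -> pd.DataFrame:
    """Read a long-format outcome table, preserving missing values.

    One row per (participant, time point, outcome) cell; duplicates are an
    integrity error; wide-format files are rejected with advice.
    """
    df = pd.read_csv(source)
    df.columns = [str(c).strip() for c in df.columns]
    if set(df.columns) != set(OUTCOME_COLUMNS):
        raise FormatError(
            "outcome table must be long format with columns "
            f"{OUTCOME_COLUMNS}; got {list(df.columns)}. Wide tables should be "
            "melted to one row per participant/time_point/outcome cell."
        )
    df = df[OUTCOME_COLUMNS]
    return validate_outcome_table(df)


def validate_outcome_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_tp = set(df["time_point"].unique()) - set(TIME_POINTS)
    if bad_tp:
        raise IntegrityError(f"unknown time points {sorted(bad_tp)}; expected {TIME_POINTS}")
    keys = df[["participant_id", "time_point", "outcome_name"]]
    dup = keys.duplicated()
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            "duplicate outcome cell for participant "
            f"{first['participant_id']!r}, {first['time_point']}, {first['outcome_name']!r}"
        )
    out = df.copy()
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    inf = np.isinf(out["value"].to_numpy(dtype=float))
    if inf.any():
        raise IntegrityError("outcome values must be finite or missing")
    return out.reset_index(drop=True)


def write_outcome_table(df: pd.DataFrame, dest: PathLike) -> None:
    """Write a long-format outcome table; missing values become empty fields."""
    validate_outcome_table(df)[OUTCOME_COLUMNS].to_csv(dest, index=False, na_rep="")


# --- run configuration -----------------------------------------------------

def load_config(source: PathLike) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError("config file must contain a YAML mapping")
    return data


def save_config(config: dict, dest: PathLike) -> None:
    text = yaml.safe_dump(config, sort_keys=True)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
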