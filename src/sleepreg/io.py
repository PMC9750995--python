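"""Data model and canonical CSV formats for per-minute actigraphy records.

The pipeline works on one-minute epochs, each scored SLEEP, WAKE or EXCLUDED
(device off / invalid), with an optional white-light illuminance reading.
Epochs are reshaped into a day-by-epoch matrix (rows are 24-h "sleep days"
anchored at a fixed clock time, 17:00 by default; columns are the 1440 minutes
of that day), which is the container the Sleep Regularity Index operates on.

Canonical file formats (all CSV, UTF-8, header required):

* epochs:     participant_id, timestamp (ISO 8601, minute precision),
              state (SLEEP|WAKE|EXCLUDED), lux (float, empty = missing)
* diary:      participant_id, day_index (1-based), drinks (int, empty =
              missing), nap_reported (0|1)
* intervals:  participant_id, kind (MAJOR|NAP), start, end (ISO 8601,
              half-open [start, end)), diary_confirmed (0|1)
* covariates: participant_id, age, sex, married, psqi, hours_slept,
              hours_in_bed (extra columns are carried through)

Raw device-export dialects (e.g. Actiware .awd) are out of scope; convert to
the canonical epoch CSV upstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "IntervalKind",
    "DayMatrix",
    "RestInterval",
    "ParticipantRecord",
    "EpochFormatError",
    "DEFAULT_DAY_START",
    "EPOCHS_PER_DAY",
    "read_epoch_csv",
    "build_day_matrix",
    "epochs_frame",
    "read_diary_csv",
    "read_intervals_csv",
    "read_covariates_csv",
    "write_epoch_csv",
    "write_diary_csv",
    "write_intervals_csv",
    "write_covariates_csv",
    "write_cohort_table",
    "read_cohort_table",
]

EPOCHS_PER_DAY = 1440
DEFAULT_DAY_START = dt.time(17, 0)

#: Fixed float formatting for all CSV output, so re-runs are byte-identical.
FLOAT_FORMAT = "%.6g"


class State(IntEnum):
    """Per-minute epoch state as scored from actigraphy."""

    WAKE = 0
    SLEEP = 1
    EXCLUDED = 2


class IntervalKind(IntEnum):
    """Rest-interval kind: MAJOR = main (night) sleep, NAP = minor rest."""

    MAJOR = 0
    NAP = 1


_STATE_FROM_STR = {s.name: s for s in State}
_KIND_FROM_STR = {k.name: k for k in IntervalKind}


class EpochFormatError(ValueError):
    """Raised for malformed canonical CSV input."""


@dataclass
class RestInterval:
    """A scored rest interval, half-open [start, end) at minute resolution.

    Naps are counted by the pipeline only when the participant's diary
    reports a nap that day, so ``diary_confirmed`` must be True for NAPs.
    """

    kind: IntervalKind
    start: dt.datetime
    end: dt.datetime
    diary_confirmed: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} must be after start {self.start}")
        if self.kind == IntervalKind.NAP and not self.diary_confirmed:
            raise ValueError("NAP intervals must be diary-confirmed")

    @property
    def duration_min(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)


@dataclass
class DayMatrix:
    """N days x 1440 one-minute epochs of sleep/wake state for one participant.

    Row ``i`` starts at ``anchor + i days`` where ``anchor`` falls on
    ``day_start_clock`` (17:00 by default, matching an evening discharge).
    Minutes never recorded are EXCLUDED.
    """

    participant_id: str
    anchor: dt.datetime
    states: np.ndarray  # (N, 1440) int8 of State values
    day_start_clock: dt.time = DEFAULT_DAY_START

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] != EPOCHS_PER_DAY:
            raise ValueError(f"states must be (N, {EPOCHS_PER_DAY}), got {self.states.shape}")
        if self.states.shape[0] < 1:
            raise ValueError("DayMatrix needs at least one day")
        if self.states.size and (self.states.min() < 0 or self.states.max() > 2):
            raise ValueError("states contains values outside {WAKE, SLEEP, EXCLUDED}")
        if self.anchor.time() != self.day_start_clock:
            raise ValueError("anchor clock time must equal day_start_clock")

    @property
    def n_days(self) -> int:
        return int(self.states.shape[0])

    @property
    def epochs_per_day(self) -> int:
        return EPOCHS_PER_DAY

    @property
    def excluded_minutes_per_day(self) -> np.ndarray:
        return (self.states == State.EXCLUDED).sum(axis=1)

    def day_start(self, day_index: int) -> dt.datetime:
        """Start datetime of 1-based day ``day_index``."""
        return self.anchor + dt.timedelta(days=day_index - 1)


@dataclass
class ParticipantRecord:
    """All per-participant inputs and derived containers for one subject."""

    id: str
    sex: str = "M"  # 'M' | 'F'
    age: float = float("nan")
    married: bool = False
    covariates: dict = field(default_factory=dict)
    epochs: pd.DataFrame | None = None  # timestamp, state, lux
    day_matrix: DayMatrix | None = None
    rest_intervals: list[RestInterval] = field(default_factory=list)
    diary: pd.DataFrame | None = None  # day_index, drinks, nap_reported

    def get_epochs(self) -> pd.DataFrame:
        """Epoch frame; materialized from the day matrix when not stored."""
        if self.epochs is not None:
            return self.epochs
        if self.day_matrix is None:
            raise ValueError(f"participant {self.id} has neither epochs nor day matrix")
        return epochs_frame(self.day_matrix)


# ---------------------------------------------------------------------------
# epoch CSV


def _parse_state_column(raw: pd.Series, path: str) -> np.ndarray:
    unknown = set(raw.unique()) - set(_STATE_FROM_STR)
    if unknown:
        raise EpochFormatError(f"{path}: unknown state value(s) {sorted(unknown)}")
    return raw.map(lambda s: int(_STATE_FROM_STR[s])).to_numpy(dtype=np.int8)


def read_epoch_csv(path) -> list[tuple[str, pd.DataFrame]]:
    """Read a canonical epoch CSV into per-participant frames.

    Returns ``[(participant_id, frame), ...]`` with frames sorted by
    timestamp and columns ``timestamp`` (datetime64), ``state`` (int8 State)
    and ``lux`` (float, NaN = missing). Participants are ordered by id.

    Raises
    ------
    EpochFormatError
        On missing columns, unparseable timestamps, unknown state strings,
        duplicate (participant, timestamp) pairs, or negative lux.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "state": str})
    required = {"participant_id", "timestamp", "state", "lux"}
    if missing := required - set(df.columns):
        raise EpochFormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        return []
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(ts.index[ts.isna()][0]) + 2  # header + 1-based
        raise EpochFormatError(f"{path}: malformed timestamp at line {line}")
    df = df.assign(timestamp=ts, state=_parse_state_column(df["state"], str(path)))
    df["lux"] = pd.to_numeric(df["lux"], errors="coerce").astype(float)
    if (df["lux"].dropna() < 0).any():
        raise EpochFormatError(f"{path}: negative lux value")
    dup = df.duplicated(subset=["participant_id", "timestamp"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise EpochFormatError(
            f"{path}: duplicate epoch for participant {row['participant_id']} at {row['timestamp']}"
        )
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        out.append((str(pid), g[["timestamp", "state", "lux"]]))
    return out


def write_epoch_csv(series: Sequence[tuple[str, pd.DataFrame]], path) -> None:
    """Write per-participant epoch frames back to the canonical CSV."""
    parts = []
    for pid, g in series:
        out = g.copy()
        out.insert(0, "participant_id", pid)
        out["state"] = [State(int(s)).name for s in out["state"]]
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        parts.append(out)
    if parts:
        pd.concat(parts).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    else:
        pd.DataFrame(columns=["participant_id", "timestamp", "state", "lux"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# day matrix


def snap_anchor(first_timestamp: dt.datetime, day_start_clock: dt.time) -> dt.datetime:
    """First occurrence of ``day_start_clock`` at or before ``first_timestamp``.

    A recording that starts after the anchor clock time that day is aligned
    back to it; the un-recorded leading minutes become EXCLUDED rather than
    shifting the day grid.
    """
    anchor = dt.datetime.combine(first_timestamp.date(), day_start_clock)
    if anchor > first_timestamp:
        anchor -= dt.timedelta(days=1)
    return anchor


def build_day_matrix(
    series: pd.DataFrame,
    participant_id: str = "",
    day_start_clock: dt.time = DEFAULT_DAY_START,
    max_days: int = 28,
) -> DayMatrix:
    """Tile an epoch series into an N x 1440 day matrix.

    Day 1 begins at the first occurrence of ``day_start_clock`` at or before
    the first record. Minutes with no record are EXCLUDED. Rows are truncated
    at ``max_days``; trailing days with no records at all are dropped.
    """
    if len(series) == 0:
        raise ValueError("empty epoch series")
    ts = pd.to_datetime(series["timestamp"])
    anchor = snap_anchor(ts.iloc[0].to_pydatetime(), day_start_clock)
    offsets = ((ts - anchor) // pd.Timedelta(minutes=1)).to_numpy()
    if offsets.min() < 0:
        raise ValueError("timestamps precede the snapped anchor; series not sorted?")
    keep = offsets < max_days * EPOCHS_PER_DAY
    offsets = offsets[keep]
    if offsets.size == 0:
        raise ValueError("no epochs fall inside the analysis window")
    n_days = int(offsets.max() // EPOCHS_PER_DAY) + 1
    states = np.full(n_days * EPOCHS_PER_DAY, int(State.EXCLUDED), dtype=np.int8)
    states[offsets] = series["state"].to_numpy(dtype=np.int8)[keep]
    return DayMatrix(
        participant_id=participant_id,
        anchor=anchor,
        states=states.reshape(n_days, EPOCHS_PER_DAY),
        day_start_clock=day_start_clock,
    )


def epochs_frame(matrix: DayMatrix, lux: np.ndarray | None = None) -> pd.DataFrame:
    """Flatten a day matrix back to a per-minute epoch frame."""
    n = matrix.n_days * EPOCHS_PER_DAY
    timestamps = pd.date_range(matrix.anchor, periods=n, freq="min")
    lux_col = np.full(n, np.nan) if lux is None else np.asarray(lux, dtype=float).reshape(n)
    return pd.DataFrame(
        {"timestamp": timestamps, "state": matrix.states.reshape(n), "lux": lux_col}
    )


# ---------------------------------------------------------------------------
# diary / intervals / covariates


def read_diary_csv(path) -> list[tuple[str, pd.DataFrame]]:
    """Read the daily diary CSV into per-participant frames.

    Returns frames with columns ``day_index`` (int), ``drinks`` (nullable
    integer — missing stays missing, never coerced to zero) and
    ``nap_reported`` (bool), sorted by day.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "day_index", "drinks", "nap_reported"}
    if missing := required - set(df.columns):
        raise EpochFormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["drinks"] = pd.array(df["drinks"], dtype="Int64")
    if (df["drinks"].dropna() < 0).any():
        raise EpochFormatError(f"{path}: negative drinks value")
    df["nap_reported"] = df["nap_reported"].astype(int).astype(bool)
    df["day_index"] = df["day_index"].astype(int)
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        if g["day_index"].duplicated().any():
            raise EpochFormatError(f"{path}: duplicate day_index for participant {pid}")
        g = g.sort_values("day_index").reset_index(drop=True)
        out.append((str(pid), g[["day_index", "drinks", "nap_reported"]]))
    return out


def write_diary_csv(diaries: Sequence[tuple[str, pd.DataFrame]], path) -> None:
    parts = []
    for pid, g in diaries:
        out = g.copy()
        out.insert(0, "participant_id", pid)
        out["nap_reported"] = out["nap_reported"].astype(int)
        parts.append(out)
    cols = ["participant_id", "day_index", "drinks", "nap_reported"]
    (pd.concat(parts) if parts else pd.DataFrame(columns=cols)).to_csv(path, index=False)


def read_intervals_csv(path) -> list[tuple[str, list[RestInterval]]]:
    """Read scored rest intervals, grouped by participant, sorted by start."""
    df = pd.read_csv(path, dtype={"participant_id": str, "kind": str})
    required = {"participant_id", "kind", "start", "end", "diary_confirmed"}
    if missing := required - set(df.columns):
        raise EpochFormatError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df["kind"].unique()) - set(_KIND_FROM_STR)
    if unknown:
        raise EpochFormatError(f"{path}: unknown interval kind(s) {sorted(unknown)}")
    df["start"] = pd.to_datetime(df["start"], format="ISO8601")
    df["end"] = pd.to_datetime(df["end"], format="ISO8601")
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("start")
        intervals = [
            RestInterval(
                kind=_KIND_FROM_STR[row.kind],
                start=row.start.to_pydatetime(),
                end=row.end.to_pydatetime(),
                diary_confirmed=bool(row.diary_confirmed),
            )
            for row in g.itertuples()
        ]
        out.append((str(pid), intervals))
    return out


def write_intervals_csv(groups: Sequence[tuple[str, Sequence[RestInterval]]], path) -> None:
    rows = [
        {
            "participant_id": pid,
            "kind": iv.kind.name,
            "start": iv.start.strftime("%Y-%m-%dT%H:%M"),
            "end": iv.end.strftime("%Y-%m-%dT%H:%M"),
            "diary_confirmed": int(iv.diary_confirmed),
        }
        for pid, ivs in groups
        for iv in ivs
    ]
    cols = ["participant_id", "kind", "start", "end", "diary_confirmed"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    """Participant covariate table indexed by participant_id."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise EpochFormatError(f"{path}: missing participant_id column")
    if df["participant_id"].duplicated().any():
        raise EpochFormatError(f"{path}: duplicate participant_id")
    return df.set_index("participant_id").sort_index()


def write_covariates_csv(df: pd.DataFrame, path) -> None:
    df.sort_index().to_csv(path, index_label="participant_id", float_format=FLOAT_FORMAT)


def write_cohort_table(table: pd.DataFrame, path) -> None:
    """Write a per-participant derived-variable table (sorted, fixed floats)."""
    out = table.sort_values("participant_id") if "participant_id" in table.columns else table
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})
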