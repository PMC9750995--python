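"""Per-day and weekly sleep, nap, light and alcohol variables.

Nightly sleep variables come from scored rest intervals laid over the epoch
grid: sleep onset latency (SOL) is the time from interval start to the first
SLEEP epoch, wake after sleep onset (WASO) counts WAKE minutes after that
onset, and actigraphy sleep efficiency is sleep time over interval duration
net of invalid (EXCLUDED) minutes. Nap minutes count only on days whose
diary reports a nap — an unreported quiet spell is not a nap.

Light exposure is thresholded at >= 250 lux per minute and summed over
24-h "light days" anchored at 22:00, split into a clock-day window
(10:00-21:59) and a clock-night window (22:00-09:59).

Alcohol variables follow the diary: relapse is any drink in the follow-up
window; a heavy drinking day is >= 4 drinks for females and >= 5 for males.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    EPOCHS_PER_DAY,
    DayMatrix,
    IntervalKind,
    ParticipantRecord,
    RestInterval,
    State,
)
from .sri import DEFAULT_WEEKS

__all__ = [
    "AlcoholSummary",
    "LIGHT_THRESHOLD_LUX",
    "DEFAULT_LIGHT_DAY_ANCHOR",
    "interval_sleep_efficiency",
    "nightly_metrics",
    "weekly_averages",
    "binarize_light",
    "light_window_minutes",
    "alcohol_summary",
    "subjective_sleep_efficiency",
]

LIGHT_THRESHOLD_LUX = 250.0
DEFAULT_LIGHT_DAY_ANCHOR = dt.time(22, 0)
#: Clock-day light window [10:00, 22:00); the complement is clock night.
DAYTIME_START = dt.time(10, 0)
DAYTIME_END = dt.time(22, 0)


@dataclass
class AlcoholSummary:
    """28-day diary-derived drinking outcome variables for one participant."""

    relapse: bool | None  # None when every drinks entry is missing
    total_drinks: int
    drinking_days: int
    heavy_drinking_days: int
    avg_drinks_per_day: float
    days_to_first_drink: float  # NaN when no drinking day
    pct_days_abstinent: float


# ---------------------------------------------------------------------------
# nightly sleep variables


def interval_sleep_efficiency(interval: RestInterval, states: np.ndarray) -> float:
    """Actigraphy sleep efficiency of one rest interval, in percent.

    ``100 * sleep_minutes / (duration - invalid_minutes)`` where invalid
    minutes are the EXCLUDED epochs inside the interval. NaN (with a
    warning) when the denominator is not positive.
    """
    states = np.asarray(states)
    if interval.duration_min < 1:
        raise ValueError("interval shorter than one minute")
    sleep = int((states == State.SLEEP).sum())
    invalid = int((states == State.EXCLUDED).sum())
    denom = interval.duration_min - invalid
    if denom <= 0:
        warnings.warn(
            f"rest interval at {interval.start} is entirely invalid; efficiency undefined",
            stacklevel=2,
        )
        return float("nan")
    return 100.0 * sleep / denom


def _interval_states(matrix: DayMatrix, interval: RestInterval) -> np.ndarray:
    """Epoch states inside an interval, clipped to the recorded grid."""
    start = int((interval.start - matrix.anchor).total_seconds() // 60)
    end = int((interval.end - matrix.anchor).total_seconds() // 60)
    flat = matrix.states.reshape(-1)
    start, end = max(start, 0), min(end, flat.size)
    return flat[start:end]


def _day_of(matrix: DayMatrix, when: dt.datetime) -> int:
    """1-based sleep-day index containing ``when``; 0 when off the grid."""
    offset = (when - matrix.anchor).total_seconds() // 60
    day = int(offset // EPOCHS_PER_DAY) + 1
    return day if 1 <= day <= matrix.n_days else 0


def nightly_metrics(record: ParticipantRecord) -> pd.DataFrame:
    """Per-day sleep variables for one participant.

    Returns one row per day of the day matrix with columns ``day_index``,
    ``sleep_duration``, ``waso``, ``sol``, ``sleep_efficiency`` and
    ``nap_duration`` (all minutes except efficiency in percent). Days
    without a major rest interval have NaN sleep variables; nap minutes are
    zero unless the diary reports a nap that day. A major interval
    containing no SLEEP epoch is scored SOL = interval length, WASO = 0,
    duration = 0 and flagged in the ``no_sleep_flag`` column.
    """
    matrix = record.day_matrix
    if matrix is None:
        raise ValueError(f"participant {record.id} has no day matrix")
    nap_reported: dict[int, bool] = {}
    if record.diary is not None:
        nap_reported = dict(
            zip(record.diary["day_index"].astype(int), record.diary["nap_reported"])
        )

    rows = []
    for day in range(1, matrix.n_days + 1):
        rows.append(
            {
                "day_index": day,
                "sleep_duration": np.nan,
                "waso": np.nan,
                "sol": np.nan,
                "sleep_efficiency": np.nan,
                "nap_duration": 0.0,
                "no_sleep_flag": False,
            }
        )
    out = pd.DataFrame(rows).set_index("day_index", drop=False)

    for interval in record.rest_intervals:
        day = _day_of(matrix, interval.start)
        if day == 0:
            continue
        if interval.kind == IntervalKind.NAP:
            if interval.diary_confirmed and nap_reported.get(day, False):
                out.loc[day, "nap_duration"] += interval.duration_min
            continue
        states = _interval_states(matrix, interval)
        sleep_idx = np.flatnonzero(states == State.SLEEP)
        if sleep_idx.size == 0:
            sol = float(interval.duration_min)
            waso = 0.0
            duration = 0.0
            out.loc[day, "no_sleep_flag"] = True
        else:
            onset = int(sleep_idx[0])
            sol = float(onset)
            waso = float((states[onset:] == State.WAKE).sum())
            duration = float(sleep_idx.size)
        out.loc[day, ["sleep_duration", "waso", "sol"]] = duration, waso, sol
        out.loc[day, "sleep_efficiency"] = interval_sleep_efficiency(interval, states)
    return out.reset_index(drop=True)


def weekly_averages(
    metrics: pd.DataFrame,
    weeks: tuple[tuple[int, int], ...] = DEFAULT_WEEKS,
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mean of per-day variables over each week window.

    The mean runs over days with data in the window (zero values count;
    NaN days do not); an empty window is NaN. Input row order is
    irrelevant — days are matched by ``day_index``.
    """
    if value_columns is None:
        value_columns = [c for c in metrics.columns if c not in ("day_index", "no_sleep_flag")]
    rows = []
    for w, (first, last) in enumerate(weeks, start=1):
        sel = metrics[(metrics["day_index"] >= first) & (metrics["day_index"] <= last)]
        row: dict = {"week": w}
        for col in value_columns:
            vals = sel[col].astype(float)
            row[col] = float(vals.mean()) if vals.notna().any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# light exposure


def binarize_light(lux: pd.Series | np.ndarray, threshold: float = LIGHT_THRESHOLD_LUX):
    """Per-minute light indicator: 1 iff lux >= threshold (inclusive).

    Missing lux stays missing and is excluded from downstream sums.
    """
    arr = pd.Series(np.asarray(lux, dtype=float))
    if (arr.dropna() < 0).any():
        raise ValueError("negative lux value")
    out = (arr >= threshold).astype(float)
    out[arr.isna()] = np.nan
    return out


def light_window_minutes(
    epochs: pd.DataFrame,
    threshold: float = LIGHT_THRESHOLD_LUX,
    light_day_anchor: dt.time = DEFAULT_LIGHT_DAY_ANCHOR,
) -> pd.DataFrame:
    """Bright-light minutes per 24-h light day, total and by clock window.

    Light days are anchored at ``light_day_anchor`` (22:00, the device
    capture start), independent of the 17:00 sleep-day anchor. Within each
    light day, minutes whose clock time falls in [10:00, 22:00) are daytime
    and the rest nighttime, so daytime + nighttime = 24-h total by
    construction. A light day with no lux reading at all is NaN.
    """
    ts = pd.to_datetime(epochs["timestamp"])
    binary = binarize_light(epochs["lux"], threshold).to_numpy()
    anchor = dt.datetime.combine(ts.iloc[0].date(), light_day_anchor)
    if anchor > ts.iloc[0]:
        anchor -= dt.timedelta(days=1)
    day_index = ((ts - anchor) // pd.Timedelta(days=1)).to_numpy() + 1
    minutes_of_day = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    in_daytime = (minutes_of_day >= DAYTIME_START.hour * 60) & (
        minutes_of_day < DAYTIME_END.hour * 60
    )

    n_days = int(day_index.max())
    observed = np.isfinite(binary)
    ones = np.nan_to_num(binary)
    total = np.bincount(day_index[observed] - 1, weights=ones[observed], minlength=n_days)
    day_obs = observed & in_daytime
    daytime = np.bincount(day_index[day_obs] - 1, weights=ones[day_obs], minlength=n_days)
    any_obs = np.bincount(day_index[observed] - 1, minlength=n_days) > 0
    out = pd.DataFrame(
        {
            "day_index": np.arange(1, n_days + 1),
            "minutes_24h": total,
            "minutes_daytime": daytime,
            "minutes_nighttime": total - daytime,
        }
    )
    out.loc[~any_obs, ["minutes_24h", "minutes_daytime", "minutes_nighttime"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# alcohol and subjective sleep


def alcohol_summary(diary: pd.DataFrame, sex: str) -> AlcoholSummary:
    """Diary-based drinking outcomes; heavy day >= 4 drinks (F) / >= 5 (M)."""
    if len(diary) == 0:
        raise ValueError("empty diary")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    drinks = pd.Series(pd.array(diary["drinks"], dtype="Int64")).reset_index(drop=True)
    observed = drinks.dropna()
    if len(observed) == 0:
        return AlcoholSummary(
            relapse=None,
            total_drinks=0,
            drinking_days=0,
            heavy_drinking_days=0,
            avg_drinks_per_day=float("nan"),
            days_to_first_drink=float("nan"),
            pct_days_abstinent=float("nan"),
        )
    heavy_threshold = 4 if sex == "F" else 5
    total = int(observed.sum())
    drinking_days = int((observed > 0).sum())
    heavy_days = int((observed >= heavy_threshold).sum())
    drank = (drinks.notna() & (drinks > 0)).to_numpy(dtype=bool)
    if drank.any():
        first = float(diary["day_index"].reset_index(drop=True)[drank].min())
    else:
        first = float("nan")
    return AlcoholSummary(
        relapse=bool(total > 0),
        total_drinks=total,
        drinking_days=drinking_days,
        heavy_drinking_days=heavy_days,
        avg_drinks_per_day=float(observed.mean()),
        days_to_first_drink=first,
        pct_days_abstinent=100.0 * (len(observed) - drinking_days) / len(observed),
    )


def subjective_sleep_efficiency(hours_slept: float, hours_in_bed: float) -> float:
    """Self-reported sleep efficiency: hours slept / hours in bed, percent.

    Capped at 100 with an over-report warning; NaN when hours in bed is
    not positive.
    """
    if hours_in_bed is None or not hours_in_bed > 0:
        return float("nan")
    pct = 100.0 * hours_slept / hours_in_bed
    if pct > 100.0:
        warnings.warn(
            f"reported sleep ({hours_slept} h) exceeds time in bed ({hours_in_bed} h); capping",
            stacklevel=2,
        )
        return 100.0
    return pct
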