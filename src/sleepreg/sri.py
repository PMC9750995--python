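"""Sleep Regularity Index (SRI) over day-by-epoch state matrices.

The SRI measures how consistent a person's sleep/wake pattern is from one
day to the next. For a matrix of N days x M one-minute epochs with state
``s[i, j]``, the index over the whole record is

    SRI = -100 + 200 / (M (N - 1)) * sum_j sum_i delta(s[i, j], s[i+1, j])

where ``delta`` is 1 when the two states are equal and 0 otherwise. A person
who sleeps and wakes at exactly the same clock times every day scores 100; a
pattern that flips state at every epoch between consecutive days scores -100.

EXCLUDED epochs (device off / invalid) carry no sleep/wake information. The
default policy drops any epoch column where either day of a pair is EXCLUDED
and renormalizes that pair's agreement by the number of remaining valid
columns; with no exclusions this reduces exactly to the formula above. The
alternative ``"as-wake"`` policy scores EXCLUDED epochs as WAKE and keeps the
fixed denominator M.

Window scores (weekly, total) are unweighted means of the per-consecutive-
day-pair scores whose both days lie inside the window; pairs straddling a
week boundary belong to no week but do enter the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import DayMatrix, State

__all__ = [
    "SRIResult",
    "DEFAULT_WEEKS",
    "pair_agreement",
    "pairwise_sri",
    "sri_over_window",
    "weekly_and_total_sri",
]

#: Week windows tiling a 28-day record, as (first_day, last_day), 1-based.
DEFAULT_WEEKS: tuple[tuple[int, int], ...] = ((1, 7), (8, 14), (15, 21), (22, 28))

_POLICIES = ("renormalize", "as-wake")


@dataclass
class SRIResult:
    """Per-participant SRI scores; missing scores are NaN, never zero."""

    participant_id: str
    total_sri: float
    weekly_sri: tuple[float, ...]
    pairwise_sri: np.ndarray  # (N-1,) float, NaN where no valid epoch pair
    valid_pairs_per_daypair: np.ndarray  # (N-1,) int
    n_days: int


def _validate_policy(excluded_policy: str) -> None:
    if excluded_policy not in _POLICIES:
        raise ValueError(f"excluded_policy must be one of {_POLICIES}")


def pair_agreement(day_a: np.ndarray, day_b: np.ndarray) -> tuple[int, int]:
    """Epoch-wise agreement between two day rows.

    A column is valid iff neither state is EXCLUDED. Returns
    ``(agree_count, valid_count)`` where ``agree_count`` counts valid columns
    with equal states.
    """
    a = np.asarray(day_a)
    b = np.asarray(day_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"day rows must be 1-D and equal length, got {a.shape} vs {b.shape}")
    valid = (a != State.EXCLUDED) & (b != State.EXCLUDED)
    agree = valid & (a == b)
    return int(agree.sum()), int(valid.sum())


def pairwise_sri(
    matrix: DayMatrix, excluded_policy: str = "renormalize"
) -> tuple[np.ndarray, np.ndarray]:
    """SRI score for every consecutive-day pair of the matrix.

    Returns ``(scores, valid_counts)`` of length N-1. A pair's score is
    ``-100 + 200 * agree / valid``; NaN when the pair has no valid epoch
    column. Under the ``"as-wake"`` policy EXCLUDED is recoded WAKE first
    and every column is valid.
    """
    _validate_policy(excluded_policy)
    if matrix.n_days < 2:
        raise ValueError("pairwise SRI needs at least 2 days")
    states = matrix.states
    if excluded_policy == "as-wake":
        states = np.where(states == State.EXCLUDED, State.WAKE, states)
    a, b = states[:-1], states[1:]
    valid = (a != State.EXCLUDED) & (b != State.EXCLUDED)
    agree = (valid & (a == b)).sum(axis=1)
    valid_counts = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = -100.0 + 200.0 * agree / valid_counts
    scores[valid_counts == 0] = np.nan
    return scores, valid_counts.astype(int)


def sri_over_window(
    matrix: DayMatrix,
    first_day: int,
    last_day: int,
    excluded_policy: str = "renormalize",
) -> float:
    """Mean of pairwise SRI scores whose both days lie in [first_day, last_day].

    Days are 1-based and inclusive. NaN when every constituent pair is
    missing (e.g. fully excluded days).
    """
    if not (1 <= first_day < last_day <= matrix.n_days):
        raise ValueError(
            f"window [{first_day}, {last_day}] invalid for a {matrix.n_days}-day matrix"
        )
    scores, _ = pairwise_sri(matrix, excluded_policy)
    window = scores[first_day - 1 : last_day - 1]  # pair i covers days i, i+1
    if np.isnan(window).all():
        return float("nan")
    return float(np.nanmean(window))


def weekly_and_total_sri(
    matrix: DayMatrix,
    weeks: tuple[tuple[int, int], ...] = DEFAULT_WEEKS,
    excluded_policy: str = "renormalize",
) -> SRIResult:
    """Weekly and total SRI for one participant.

    Each week window that fits inside the record gets the mean of its
    interior pairwise scores; windows beyond the data are NaN. The total is
    the mean over all N-1 pairs, so pairs straddling week boundaries count
    toward the total even though they belong to no week.
    """
    scores, valid_counts = pairwise_sri(matrix, excluded_policy)
    weekly = []
    for first, last in weeks:
        last = min(last, matrix.n_days)
        if first >= last:
            weekly.append(float("nan"))
        else:
            weekly.append(sri_over_window(matrix, first, last, excluded_policy))
    total = float(np.nanmean(scores)) if not np.isnan(scores).all() else float("nan")
    return SRIResult(
        participant_id=matrix.participant_id,
        total_sri=total,
        weekly_sri=tuple(weekly),
        pairwise_sri=scores,
        valid_pairs_per_daypair=valid_counts,
        n_days=matrix.n_days,
    )


def closed_form_sri(states: np.ndarray) -> float:
    """Direct double-sum evaluation of the SRI formula (no exclusions).

    Equals the mean-of-pairwise path exactly when the matrix has no
    EXCLUDED epochs; kept as an explicit cross-check of the window
    semantics, not as the production path.
    """
    s = np.asarray(states)
    n, m = s.shape
    if n < 2:
        raise ValueError("need at least 2 days")
    if (s == State.EXCLUDED).any():
        raise ValueError("closed form is defined for fully observed matrices")
    agree = int((s[:-1] == s[1:]).sum())
    return -100.0 + 200.0 / (m * (n - 1)) * agree


def is_missing(score: float) -> bool:
    return isinstance(score, float) and math.isnan(score)
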