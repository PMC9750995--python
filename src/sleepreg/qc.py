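"""Participant-level inclusion rules for actigraphy completeness.

A participant's record enters the analysis only when it is long enough and
complete enough to support the regularity metrics:

* at least ``min_days`` days containing any non-excluded data (default 7,
  not necessarily consecutive), and
* at most ``max_high_exclusion_days`` days (default 1) carrying
  ``high_exclusion_hours`` (default 6.0) or more hours of EXCLUDED minutes —
  the allowance covers watch removal for showers, bathing or swimming.

Both boundaries are inclusive: a day with exactly 6.0 excluded hours counts
against the allowance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DayMatrix, ParticipantRecord, State

__all__ = [
    "QCRule",
    "QCReport",
    "excluded_hours_per_day",
    "passes_inclusion",
    "filter_cohort",
]

#: Rule identifiers reported for filtered participants.
MIN_DAYS = "MIN_DAYS"
EXCLUDED_DAYS = "EXCLUDED_DAYS"


@dataclass
class QCRule:
    min_days: int = 7
    high_exclusion_hours: float = 6.0
    max_high_exclusion_days: int = 1


@dataclass
class QCReport:
    participant_id: str
    n_days_with_data: int
    n_days_with_ge6h_excluded: int
    included: bool
    reasons: list[str] = field(default_factory=list)


def excluded_hours_per_day(matrix: DayMatrix) -> np.ndarray:
    """EXCLUDED minutes of each day row, in hours."""
    return matrix.excluded_minutes_per_day / 60.0


def passes_inclusion(matrix: DayMatrix, rule: QCRule = QCRule()) -> QCReport:
    """Evaluate the inclusion rules on one participant's day matrix."""
    has_data = (matrix.states != State.EXCLUDED).any(axis=1)
    n_days_with_data = int(has_data.sum())
    hours = excluded_hours_per_day(matrix)
    n_bad = int((hours >= rule.high_exclusion_hours).sum())
    reasons = []
    if n_days_with_data < rule.min_days:
        reasons.append(MIN_DAYS)
    if n_bad > rule.max_high_exclusion_days:
        reasons.append(EXCLUDED_DAYS)
    return QCReport(
        participant_id=matrix.participant_id,
        n_days_with_data=n_days_with_data,
        n_days_with_ge6h_excluded=n_bad,
        included=not reasons,
        reasons=reasons,
    )


def filter_cohort(
    records: list[ParticipantRecord], rule: QCRule = QCRule()
) -> tuple[list[ParticipantRecord], list[QCReport]]:
    """Order-preserving partition of a cohort by the inclusion rules.

    Returns the included records and one report per input record.
    Participants with no day matrix at all fail the minimum-days rule.
    """
    included: list[ParticipantRecord] = []
    reports: list[QCReport] = []
    for rec in records:
        if rec.day_matrix is None:
            reports.append(
                QCReport(rec.id, 0, 0, included=False, reasons=[MIN_DAYS])
            )
            continue
        report = passes_inclusion(rec.day_matrix, rule)
        reports.append(report)
        if report.included:
            included.append(rec)
    return included, reports
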