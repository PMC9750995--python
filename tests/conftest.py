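import datetime as dt

import numpy as np
import pytest

from sleepreg.io import EPOCHS_PER_DAY, DayMatrix, State
from sleepreg.simulate import GeneratorConfig, generate_cohort

ANCHOR = dt.datetime(2024, 1, 5, 17, 0)


def day_row(sleep_start: int = 390, sleep_len: int = 450) -> np.ndarray:
    """A 1440-minute day: WAKE with one SLEEP block (23:30-07:00 default)."""
    row = np.zeros(EPOCHS_PER_DAY, dtype=np.int8)
    row[sleep_start : sleep_start + sleep_len] = State.SLEEP
    return row


def matrix_from_rows(rows, pid="T") -> DayMatrix:
    return DayMatrix(pid, ANCHOR, np.stack(rows))


@pytest.fixture(scope="session")
def identical_28day_matrix() -> DayMatrix:
    return matrix_from_rows([day_row()] * 28)


@pytest.fixture(scope="session")
def small_cohort():
    """40 synthetic participants with light and diaries (shared, read-only)."""
    cfg = GeneratorConfig(seed=11, n_participants=40)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without missingness mechanisms: every participant passes QC."""
    cfg = GeneratorConfig(
        seed=12,
        n_participants=60,
        include_light=False,
        short_wear_probability=0.0,
        heavy_exclusion_probability=0.0,
        excluded_day_probability=0.0,
    )
    return generate_cohort(cfg)
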