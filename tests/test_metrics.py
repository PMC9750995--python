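"""Sleep, nap, light and alcohol variable derivations."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sleepreg.io import (
    EPOCHS_PER_DAY,
    DayMatrix,
    IntervalKind,
    ParticipantRecord,
    RestInterval,
    State,
)
from sleepreg.metrics import (
    alcohol_summary,
    binarize_light,
    interval_sleep_efficiency,
    light_window_minutes,
    nightly_metrics,
    subjective_sleep_efficiency,
    weekly_averages,
)

from conftest import ANCHOR, day_row, matrix_from_rows

S, W, X = State.SLEEP, State.WAKE, State.EXCLUDED


def _interval(start_min, length):
    return RestInterval(
        IntervalKind.MAJOR,
        ANCHOR + dt.timedelta(minutes=start_min),
        ANCHOR + dt.timedelta(minutes=start_min + length),
    )


class TestIntervalSleepEfficiency:
    def test_all_sleep_no_invalid(self):
        states = np.full(480, S, dtype=np.int8)
        assert interval_sleep_efficiency(_interval(390, 480), states) == 100.0

    def test_partial_sleep(self):
        states = np.concatenate([np.full(400, S), np.full(80, W)]).astype(np.int8)
        assert interval_sleep_efficiency(_interval(390, 480), states) == pytest.approx(
            100 * 400 / 480
        )

    def test_invalid_minutes_shrink_denominator(self):
        states = np.concatenate([np.full(400, S), np.full(80, X)]).astype(np.int8)
        assert interval_sleep_efficiency(_interval(390, 480), states) == pytest.approx(100.0)

    def test_all_invalid_is_missing_with_warning(self):
        states = np.full(60, X, dtype=np.int8)
        with pytest.warns(UserWarning, match="invalid"):
            assert np.isnan(interval_sleep_efficiency(_interval(390, 60), states))


class TestNightlyMetrics:
    def _record(self, row, intervals, diary=None):
        return ParticipantRecord(
            id="T",
            day_matrix=DayMatrix("T", ANCHOR, row[None, :]),
            rest_intervals=intervals,
            diary=diary,
        )

    def test_sol_counts_leading_wake(self):
        row = np.zeros(EPOCHS_PER_DAY, dtype=np.int8)
        row[392:870] = S  # interval starts 390: 2 wake minutes then sleep
        m = nightly_metrics(self._record(row, [_interval(390, 480)]))
        assert m.loc[0, "sol"] == 2
        assert m.loc[0, "waso"] == 0
        assert m.loc[0, "sleep_duration"] == 478

    def test_waso_counts_wake_after_onset(self):
        row = np.zeros(EPOCHS_PER_DAY, dtype=np.int8)
        row[390:870] = S
        row[500:530] = W  # 30 interior wake minutes
        m = nightly_metrics(self._record(row, [_interval(390, 480)]))
        assert m.loc[0, "waso"] == 30
        assert m.loc[0, "sol"] == 0

    def test_interval_without_sleep_flagged(self):
        row = np.zeros(EPOCHS_PER_DAY, dtype=np.int8)
        m = nightly_metrics(self._record(row, [_interval(390, 120)]))
        assert m.loc[0, "sol"] == 120
        assert m.loc[0, "waso"] == 0
        assert m.loc[0, "sleep_duration"] == 0
        assert bool(m.loc[0, "no_sleep_flag"])

    def test_unreported_nap_not_counted(self):
        row = day_row()
        row[1200:1260] = S  # daytime rest
        nap = RestInterval(
            IntervalKind.NAP,
            ANCHOR + dt.timedelta(minutes=1200),
            ANCHOR + dt.timedelta(minutes=1260),
            diary_confirmed=True,
        )
        diary_no = pd.DataFrame({"day_index": [1], "drinks": [0], "nap_reported": [False]})
        diary_yes = pd.DataFrame({"day_index": [1], "drinks": [0], "nap_reported": [True]})
        m_no = nightly_metrics(self._record(row, [nap], diary_no))
        m_yes = nightly_metrics(self._record(row, [nap], diary_yes))
        assert m_no.loc[0, "nap_duration"] == 0
        assert m_yes.loc[0, "nap_duration"] == 60


class TestWeeklyAverages:
    def test_constant_duration(self):
        df = pd.DataFrame(
            {"day_index": range(1, 29), "sleep_duration": [450.0] * 28}
        )
        weekly = weekly_averages(df, value_columns=["sleep_duration"])
        assert (weekly["sleep_duration"] == 450.0).all()

    def test_zero_nap_days_enter_denominator(self):
        naps = [0.0] * 28
        naps[1], naps[3] = 100.0, 140.0
        df = pd.DataFrame({"day_index": range(1, 29), "nap_duration": naps})
        weekly = weekly_averages(df, value_columns=["nap_duration"])
        assert weekly["nap_duration"].iloc[0] == pytest.approx(240 / 7)

    def test_empty_week_is_missing(self):
        df = pd.DataFrame({"day_index": range(1, 8), "waso": [10.0] * 7})
        weekly = weekly_averages(df, value_columns=["waso"])
        assert np.isnan(weekly["waso"].iloc[1])

    def test_row_order_irrelevant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"day_index": range(1, 29), "nap_duration": rng.integers(0, 120, 28)}
        )
        shuffled = df.sample(frac=1, random_state=2)
        a = weekly_averages(df, value_columns=["nap_duration"])
        b = weekly_averages(shuffled, value_columns=["nap_duration"])
        pd.testing.assert_frame_equal(a, b)


class TestLight:
    def test_threshold_inclusive(self):
        out = binarize_light(pd.Series([250.0, 249.9, np.nan]))
        assert out.iloc[0] == 1.0
        assert out.iloc[1] == 0.0
        assert np.isnan(out.iloc[2])

    def test_negative_lux_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            binarize_light(pd.Series([-1.0]))

    def _epochs(self, lux):
        start = dt.datetime(2024, 1, 5, 22, 0)
        n = len(lux)
        return pd.DataFrame(
            {
                "timestamp": pd.date_range(start, periods=n, freq="min"),
                "state": np.zeros(n, dtype=np.int8),
                "lux": lux,
            }
        )

    def test_daytime_window_only(self):
        # bright exactly during 10:00-21:59, dark otherwise
        lux = np.zeros(EPOCHS_PER_DAY)
        minutes = (np.arange(EPOCHS_PER_DAY) + 22 * 60) % (24 * 60)
        daytime = (minutes >= 600) & (minutes < 1320)
        lux[daytime] = 300.0
        day = light_window_minutes(self._epochs(lux)).iloc[0]
        assert (day["minutes_24h"], day["minutes_daytime"], day["minutes_nighttime"]) == (
            720,
            720,
            0,
        )

    def test_all_dark_day(self):
        day = light_window_minutes(self._epochs(np.zeros(EPOCHS_PER_DAY))).iloc[0]
        assert (day["minutes_24h"], day["minutes_daytime"], day["minutes_nighttime"]) == (
            0,
            0,
            0,
        )

    def test_alternating_light(self):
        lux = np.where(np.arange(EPOCHS_PER_DAY) % 2 == 0, 400.0, 0.0)
        day = light_window_minutes(self._epochs(lux)).iloc[0]
        assert day["minutes_24h"] == 720
        assert day["minutes_daytime"] == 360
        assert day["minutes_nighttime"] == 360

    def test_all_missing_day_is_missing(self):
        day = light_window_minutes(self._epochs(np.full(EPOCHS_PER_DAY, np.nan))).iloc[0]
        assert np.isnan(day["minutes_24h"])

    def test_conservation_on_random_days(self):
        rng = np.random.default_rng(9)
        lux = rng.lognormal(3, 2, 3 * EPOCHS_PER_DAY)
        lux[rng.random(lux.size) < 0.05] = np.nan
        days = light_window_minutes(self._epochs(lux))
        ok = days.dropna()
        np.testing.assert_allclose(
            ok["minutes_daytime"] + ok["minutes_nighttime"], ok["minutes_24h"]
        )


class TestAlcohol:
    def _diary(self, drinks):
        return pd.DataFrame(
            {
                "day_index": range(1, len(drinks) + 1),
                "drinks": pd.array(drinks, dtype="Int64"),
                "nap_reported": [False] * len(drinks),
            }
        )

    def test_female_four_drinks_is_heavy(self):
        s = alcohol_summary(self._diary([0, 4, 0]), "F")
        assert s.relapse is True
        assert s.heavy_drinking_days == 1
        assert s.days_to_first_drink == 2

    def test_male_four_drinks_not_heavy(self):
        s = alcohol_summary(self._diary([0, 4, 0]), "M")
        assert s.heavy_drinking_days == 0
        assert s.drinking_days == 1

    def test_abstinent_diary(self):
        s = alcohol_summary(self._diary([0] * 28), "M")
        assert s.relapse is False
        assert s.pct_days_abstinent == 100.0
        assert np.isnan(s.days_to_first_drink)

    def test_all_missing_relapse_unknown(self):
        s = alcohol_summary(self._diary([None] * 5), "M")
        assert s.relapse is None

    def test_internal_consistency(self, small_cohort):
        records, _ = small_cohort
        for rec in records[:15]:
            s = alcohol_summary(rec.diary, rec.sex)
            drinks = rec.diary["drinks"]
            zero_days = int((drinks == 0).sum())
            missing = int(drinks.isna().sum())
            assert s.drinking_days + zero_days + missing == len(rec.diary)
            assert s.heavy_drinking_days <= s.drinking_days


class TestSubjectiveSleepEfficiency:
    def test_seven_of_eight_hours(self):
        assert subjective_sleep_efficiency(7, 8) == pytest.approx(87.5)

    def test_equal_hours(self):
        assert subjective_sleep_efficiency(8, 8) == 100.0

    def test_overreport_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert subjective_sleep_efficiency(9, 8) == 100.0

    def test_nonpositive_bed_time_missing(self):
        assert np.isnan(subjective_sleep_efficiency(7, 0))
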