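"""Sleep Regularity Index: formula identities, exclusions, window semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sleepreg.io import EPOCHS_PER_DAY, State
from sleepreg.sri import (
    DEFAULT_WEEKS,
    closed_form_sri,
    pair_agreement,
    pairwise_sri,
    sri_over_window,
    weekly_and_total_sri,
)

from conftest import day_row, matrix_from_rows

S, W, X = State.SLEEP, State.WAKE, State.EXCLUDED


def triple_loop_sri(states: np.ndarray) -> float:
    """Independent oracle: literal epoch-by-epoch double sum, no vectorization."""
    n, m = states.shape
    total = 0
    for j in range(m):
        for i in range(n - 1):
            total += int(states[i, j] == states[i + 1, j])
    return -100.0 + 200.0 / (m * (n - 1)) * total


class TestPairAgreement:
    def test_identical_full_rows(self):
        row = day_row()
        assert pair_agreement(row, row) == (EPOCHS_PER_DAY, EPOCHS_PER_DAY)

    def test_enumerated_four_columns(self):
        # columns: (S,S) agree, (S,W) disagree, (W,W) agree, (W,W) agree
        assert pair_agreement([S, S, W, W], [S, W, W, W]) == (3, 4)

    def test_excluded_column_skipped(self):
        assert pair_agreement([S, X, W, W], [S, S, W, W]) == (3, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pair_agreement([S, W], [S, W, W])


class TestPairwiseSri:
    def test_identical_days_score_100(self):
        m = matrix_from_rows([day_row(), day_row()])
        scores, valid = pairwise_sri(m)
        assert scores[0] == 100.0
        assert valid[0] == EPOCHS_PER_DAY

    def test_complementary_days_score_minus_100(self):
        row = day_row()
        m = matrix_from_rows([row, 1 - row])
        scores, _ = pairwise_sri(m)
        assert scores[0] == -100.0

    def test_three_quarters_agreement_scores_50(self):
        # 3 agreements in 4 valid columns, tiled to fill a day
        a = np.tile(np.array([S, S, W, W], dtype=np.int8), EPOCHS_PER_DAY // 4)
        b = np.tile(np.array([S, W, W, W], dtype=np.int8), EPOCHS_PER_DAY // 4)
        scores, _ = pairwise_sri(matrix_from_rows([a, b]))
        assert scores[0] == pytest.approx(-100 + 200 * 0.75)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_sri(matrix_from_rows([day_row()]))

    def test_fully_excluded_pair_is_missing(self):
        rows = [day_row(), np.full(EPOCHS_PER_DAY, X, dtype=np.int8), day_row()]
        scores, valid = pairwise_sri(matrix_from_rows(rows))
        assert np.isnan(scores).all()
        assert (valid == 0).all()

    def test_as_wake_policy_keeps_full_denominator(self):
        a = day_row()
        b = a.copy()
        b[390:490] = X  # excluded during sleep -> scored as WAKE under as-wake
        m = matrix_from_rows([a, b])
        renorm, valid_r = pairwise_sri(m, "renormalize")
        aswake, valid_w = pairwise_sri(m, "as-wake")
        assert valid_r[0] == EPOCHS_PER_DAY - 100
        assert valid_w[0] == EPOCHS_PER_DAY
        assert renorm[0] == 100.0
        # columns 0..99 hold SLEEP vs (EXCLUDED->WAKE): 100 disagreements
        assert aswake[0] == pytest.approx(-100 + 200 * (EPOCHS_PER_DAY - 100) / EPOCHS_PER_DAY)


class TestWindows:
    def test_toy_three_day_window_equals_closed_form(self):
        a = np.tile(np.array([S, S, W, W], dtype=np.int8), EPOCHS_PER_DAY // 4)
        b = np.tile(np.array([S, W, W, W], dtype=np.int8), EPOCHS_PER_DAY // 4)
        m = matrix_from_rows([a, b, a])
        score = sri_over_window(m, 1, 3)
        assert score == pytest.approx(50.0)
        assert score == pytest.approx(closed_form_sri(m.states))
        assert score == pytest.approx(triple_loop_sri(m.states))

    def test_window_shorter_than_two_days_rejected(self):
        m = matrix_from_rows([day_row()] * 3)
        with pytest.raises(ValueError):
            sri_over_window(m, 2, 2)

    def test_all_excluded_window_is_missing(self):
        blank = np.full(EPOCHS_PER_DAY, X, dtype=np.int8)
        m = matrix_from_rows([blank, blank, day_row()])
        assert np.isnan(sri_over_window(m, 1, 2))


class TestWeeklyAndTotal:
    def test_identical_28_days_all_100(self, identical_28day_matrix):
        res = weekly_and_total_sri(identical_28day_matrix)
        assert res.total_sri == 100.0
        assert res.weekly_sri == (100.0,) * 4

    def test_seven_day_record_only_week1(self):
        m = matrix_from_rows([day_row()] * 7)
        res = weekly_and_total_sri(m)
        assert res.weekly_sri[0] == 100.0
        assert all(np.isnan(s) for s in res.weekly_sri[1:])
        assert res.total_sri == res.weekly_sri[0]

    def test_disrupted_final_week_scores_lower(self):
        rows = [day_row() for _ in range(21)]
        # week 4: bedtime shifted by ±12 h alternating nights
        for d in range(7):
            shift = 720 if d % 2 else 0
            rows.append(day_row(sleep_start=(390 + shift) % EPOCHS_PER_DAY))
        res = weekly_and_total_sri(matrix_from_rows(rows))
        assert res.weekly_sri[3] < res.weekly_sri[0]
        # cross-check the total against the independent brute-force oracle
        assert res.total_sri == pytest.approx(triple_loop_sri(np.stack(rows)))

    def test_boundary_pairs_enter_total_not_weeks(self):
        # 8 days: days 1-7 identical, day 8 complementary; the 7->8 pair
        # belongs to no week but must pull the total below 100.
        rows = [day_row()] * 7 + [1 - day_row()]
        m = matrix_from_rows(rows)
        res = weekly_and_total_sri(m, weeks=((1, 7), (8, 14)))
        assert res.weekly_sri[0] == 100.0
        assert res.total_sri == pytest.approx((6 * 100 + (-100)) / 7)


@pytest.fixture(scope="module")
def random_small_matrices():
    rng = np.random.default_rng(123)
    out = []
    for _ in range(50):
        n = rng.integers(2, 7)
        m4 = rng.integers(2, 25)
        out.append(rng.integers(0, 2, size=(n, m4)).astype(np.int8))
    return out


class TestInvariants:
    def test_mean_of_pairwise_equals_closed_form(self, random_small_matrices):
        for states in random_small_matrices:
            m4 = states.shape[1]
            # build a day-sized matrix embedding the toy pattern tiled
            reps = EPOCHS_PER_DAY // m4
            tiled = np.tile(states, (1, reps))
            pad = EPOCHS_PER_DAY - tiled.shape[1]
            full = np.concatenate([tiled, tiled[:, :pad]], axis=1)
            dm = matrix_from_rows(list(full))
            scores, _ = pairwise_sri(dm)
            assert np.nanmean(scores) == pytest.approx(
                triple_loop_sri(full), abs=1e-9
            )

    def test_scores_bounded(self, small_cohort):
        records, _ = small_cohort
        for rec in records[:10]:
            scores, _ = pairwise_sri(rec.day_matrix)
            finite = scores[np.isfinite(scores)]
            assert ((finite >= -100) & (finite <= 100)).all()

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = [day_row(sleep_start=int(390 + rng.integers(-60, 60))) for _ in range(6)]
        m = matrix_from_rows(rows)
        perm = rng.permutation(EPOCHS_PER_DAY)
        mp = matrix_from_rows([r[perm] for r in rows])
        np.testing.assert_allclose(pairwise_sri(m)[0], pairwise_sri(mp)[0])

    def test_sleep_wake_label_swap_invariance(self):
        rows = [day_row(sleep_start=390 + 17 * d) for d in range(5)]
        m = matrix_from_rows(rows)
        swapped = matrix_from_rows([1 - r for r in rows])
        np.testing.assert_allclose(pairwise_sri(m)[0], pairwise_sri(swapped)[0])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        states=hnp.arrays(
            np.int8,
            shape=st.tuples(st.integers(2, 5), st.just(12)),
            elements=st.integers(0, 2),
        )
    )
    def test_pairwise_scores_bounded_and_renormalized(self, states):
        """Any mix of sleep/wake/excluded yields scores in [-100, 100] with
        valid counts never exceeding the row length."""
        reps = EPOCHS_PER_DAY // 12
        full = np.tile(states, (1, reps))
        scores, valid = pairwise_sri(matrix_from_rows(list(full)))
        finite = scores[np.isfinite(scores)]
        assert ((finite >= -100) & (finite <= 100)).all()
        assert (valid <= EPOCHS_PER_DAY).all()
        # per-pair oracle: recompute agreement by hand
        for i in range(full.shape[0] - 1):
            agree, v = pair_agreement(full[i], full[i + 1])
            assert valid[i] == v
            if v:
                assert scores[i] == pytest.approx(-100 + 200 * agree / v)
            else:
                assert np.isnan(scores[i])

    def test_adding_exclusions_never_raises_valid_count(self):
        rng = np.random.default_rng(6)
        rows = [day_row(), day_row(400)]
        m = matrix_from_rows(rows)
        _, valid0 = pairwise_sri(m)
        corrupted = [r.copy() for r in rows]
        for r in corrupted:
            idx = rng.choice(EPOCHS_PER_DAY, 200, replace=False)
            r[idx] = X
        _, valid1 = pairwise_sri(matrix_from_rows(corrupted))
        assert (valid1 <= valid0).all()
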