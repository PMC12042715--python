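"""MMA curve arithmetic, period segmentation, and trend fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lcgate.learning_curve import (
    fit_trend,
    major_indicators,
    mma_series,
    round_half_up,
    segment_periods,
    tct_series,
)
from lcgate.records_io import AttemptRecord


def brute_force_mma(indicators):
    """Independent oracle: recount majors from scratch at every n."""
    return [sum(indicators[:n]) / n for n in range(1, len(indicators) + 1)]


class TestIndicators:
    def test_sample_major_positions(self, sample_records):
        ind = major_indicators(sample_records)
        assert list(np.nonzero(ind)[0] + 1) == [6, 13, 14, 16]
        assert len(ind) == 18

    def test_noncontiguous_records_rejected(self):
        recs = [
            AttemptRecord(attempt_index=i, total_score=0, total_time=1)
            for i in (1, 3)
        ]
        with pytest.raises(ValueError, match="contiguous"):
            major_indicators(recs)

    @pytest.mark.parametrize("score,expected", [(0, 0), (5, 1)])
    def test_uniform_scores(self, score, expected):
        recs = [
            AttemptRecord(attempt_index=i, total_score=score, total_time=0)
            for i in range(1, 8)
        ]
        assert list(major_indicators(recs)) == [expected] * 7


class TestMMASeries:
    def test_first_major_at_attempt_six(self):
        ind = [0, 0, 0, 0, 0, 1]
        assert mma_series(ind).at(6) == pytest.approx(1 / 6, abs=1e-12)

    def test_peak_after_five_majors_in_nineteen(self):
        ind = np.zeros(19, dtype=int)
        ind[[5, 12, 13, 15, 18]] = 1
        series = mma_series(ind)
        assert series.at(19) == pytest.approx(5 / 19, abs=1e-12)
        assert round_half_up(series.at(19), 3) == 0.263

    def test_no_majors_is_identically_zero(self):
        assert np.all(mma_series([0] * 40).values == 0.0)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, ind):
        np.testing.assert_allclose(
            mma_series(ind).values, brute_force_mma(ind), atol=1e-12
        )

    def test_oracle_agreement_on_long_random_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(2, 1000))
            ind = (rng.random(n) < rng.uniform(0.02, 0.5)).astype(int)
            np.testing.assert_allclose(
                mma_series(ind).values, brute_force_mma(list(ind)), atol=1e-12
            )

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=100))
    def test_appending_non_major_strictly_decreases_positive_mma(self, ind):
        final = mma_series(ind).values[-1]
        extended = mma_series(ind + [0]).values[-1]
        if final > 0:
            assert extended < final
        else:
            assert extended == 0.0

    def test_rejects_empty_and_nonbinary(self):
        with pytest.raises(ValueError):
            mma_series([])
        with pytest.raises(ValueError):
            mma_series([0, 2, 1])


class TestSegmentation:
    def test_reconstructed_trial_period_table(self, full_trial_indicators):
        series = mma_series(full_trial_indicators)
        periods = segment_periods(series, full_trial_indicators, [5, 12, 19, 36, 85])
        assert len(periods) == 6
        p4, p5, p6 = periods[3], periods[4], periods[5]
        assert (p4.start_attempt, p4.end_attempt, p4.noa) == (20, 36, 17)
        assert p4.mma_start == pytest.approx(5 / 19)
        assert p4.mma_end == pytest.approx(6 / 36)
        assert round_half_up(p4.absolute_drop, 3) == 0.096
        assert round_half_up(p4.drop_rate, 3) == 0.006
        assert round_half_up(p5.absolute_drop, 3) == 0.049
        assert round_half_up(p5.drop_rate, 3) == 0.001
        assert round_half_up(p6.mma_end, 3) == 0.091

    def test_whole_range_when_no_breakpoints(self):
        ind = [0, 0, 0, 0]
        periods = segment_periods(mma_series(ind), ind, [])
        assert len(periods) == 1
        assert periods[0].absolute_drop == 0.0
        assert periods[0].drop_rate == 0.0

    def test_breakpoint_outside_range_rejected(self):
        ind = [0, 1, 0]
        with pytest.raises(ValueError):
            segment_periods(mma_series(ind), ind, [3])

    def test_major_counts_conserved_and_drops_telescope(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 300))
            ind = (rng.random(n) < 0.2).astype(int)
            n_bp = int(rng.integers(0, 5))
            bps = sorted(rng.choice(np.arange(1, n), size=n_bp, replace=False))
            series = mma_series(ind)
            periods = segment_periods(series, ind, list(bps))
            assert sum(p.n_major_in_period for p in periods) == ind.sum()
            telescoped = sum(p.absolute_drop for p in periods)
            assert telescoped == pytest.approx(0.0 - series.at(n), abs=1e-12)
            # drop_rate * noa == absolute_drop, per period
            for p in periods:
                assert p.drop_rate * p.noa == pytest.approx(p.absolute_drop)

    def test_period_tct_average_includes_untimed_attempts(self, sample_records):
        ind = major_indicators(sample_records)
        series = mma_series(ind)
        periods = segment_periods(series, ind, [5, 12], records=sample_records)
        # attempts 1-5 are all timed: plain mean
        assert periods[0].tct_average == pytest.approx(2523.0)
        # attempts 6-12 include one aborted (0 s) attempt in the denominator
        assert periods[1].tct_average == pytest.approx(11988 / 7)


class TestTCTSeries:
    def test_sample_excludes_aborted_attempts(self, sample_records):
        series = tct_series(sample_records)
        assert len(series) == 14
        attempts = [a for a, _ in series]
        assert all(a not in (6, 13, 14, 16) for a in attempts)
        assert max(t for _, t in series) == 3057
        assert dict(series)[4] == 3057

    def test_all_major_log_yields_empty_series(self):
        recs = [
            AttemptRecord(attempt_index=i, total_score=5, total_time=0)
            for i in range(1, 5)
        ]
        assert tct_series(recs) == []


class TestTrendFit:
    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        fit = fit_trend(x, 2 * x + 1, "linear")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_exponential_recovery(self):
        x = np.arange(1.0, 40.0)
        y = 3.0 * np.exp(-0.05 * x)
        fit = fit_trend(x, y, "exponential")
        assert fit.slope == pytest.approx(-0.05, abs=1e-10)
        assert math.exp(fit.intercept) == pytest.approx(3.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols_on_fixed_noisy_table(self):
        # small fixed table; oracle is the textbook closed-form OLS solution
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        noise = np.array([0.3, -0.1, 0.2, -0.4, 0.1, -0.1])
        y = 2 * x + 1 + noise
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        fit = fit_trend(x, y, "linear")
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        resid = y - (intercept + slope * x)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_slope_and_r2_invariant_to_x_shift(self):
        rng = np.random.default_rng(5)
        x = np.arange(20.0)
        y = 3 * x + rng.normal(0, 2, size=20)
        base = fit_trend(x, y, "linear")
        shifted = fit_trend(x + 137.0, y, "linear")
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        assert shifted.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_constant_y_reports_nan_r2(self):
        fit = fit_trend([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0], "linear")
        assert math.isnan(fit.r_squared)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exponential_requires_positive_y(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2, 3], [1.0, 0.0, 2.0], "exponential")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2], [1.0, 2.0], "linear")


@pytest.mark.parametrize(
    "value,decimals,expected",
    [(0.0965, 3, 0.097), (0.2631578, 3, 0.263), (0.0005689, 4, 0.0006), (-1.25, 1, -1.3)],
)
def test_round_half_up_ties_away_from_zero(value, decimals, expected):
    assert round_half_up(value, decimals) == expected
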