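"""Per-user trend regression and the Improver/Decliner analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dietcohort import TrendClass, classify_cohort_trends, compare_improvers, fit_user_trend
from dietcohort.trends import InsufficientDataError


class TestFitUserTrend:
    def test_hand_computed_slope(self):
        res = fit_user_trend([0.2, 0.4, 0.3, 0.5])
        assert res.slope == pytest.approx(0.08)  # Sxy = 0.4, Sxx = 5
        assert res.n_points == 4

    def test_constant_series_no_trend(self):
        res = fit_user_trend([0.5] * 10)
        assert res.slope == 0.0
        assert res.classification is TrendClass.NO_TREND

    def test_noiseless_ramp_is_improver(self):
        res = fit_user_trend(np.linspace(0.2, 0.8, 12))
        assert res.classification is TrendClass.IMPROVER
        assert res.p_value < 1e-50  # residuals vanish up to floating error

    def test_noiseless_decline_is_decliner(self):
        res = fit_user_trend(np.linspace(0.8, 0.2, 12))
        assert res.classification is TrendClass.DECLINER

    def test_too_few_points_signals(self):
        with pytest.raises(InsufficientDataError):
            fit_user_trend([0.1, 0.2])

    @given(
        y=st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=60),
        alpha=st.sampled_from([0.01, 0.05, 0.2]),
    )
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_matches_linregress_and_classification_invariant(self, y, alpha):
        res = fit_user_trend(y, alpha=alpha)
        ref = stats.linregress(np.arange(1, len(y) + 1), y)
        assert res.slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-12)
        if np.ptp(y) > 0 and res.p_value > 0 and np.isfinite(ref.pvalue):
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)
        assert (res.classification is TrendClass.IMPROVER) == (
            res.slope > 0 and res.p_value < alpha
        )
        assert (res.classification is TrendClass.DECLINER) == (
            res.slope < 0 and res.p_value < alpha
        )

    @given(y=st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_reversal_negates_slope_preserves_p(self, y):
        fwd = fit_user_trend(y)
        rev = fit_user_trend(y[::-1])
        assert rev.slope == pytest.approx(-fwd.slope, abs=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-9)


def _toy_cohort_frames(series_by_user):
    """Build minimal user/picture summary frames for trend classification."""
    from dietcohort import Adherence

    users = pd.DataFrame(
        {
            "user_id": list(series_by_user),
            "first_valid_picture_id": [f"{u}_p1" for u in series_by_user],
            "n_valid_pictures": [len(v) for v in series_by_user.values()],
            "usage_period_days": [30.0] * len(series_by_user),
            "pictures_per_day": [1.0] * len(series_by_user),
        }
    )
    users["adherence"] = Adherence.ACTIVE
    rows = []
    for uid, vals in series_by_user.items():
        for i, v in enumerate(vals, start=1):
            rows.append((uid, f"{uid}_p{i}", i, v, True))
    pictures = pd.DataFrame(
        rows, columns=["user_id", "picture_id", "ordinal", "avg_peer_rating", "counted"]
    )
    return users, pictures


class TestCohortTrends:
    def test_all_noiseless_ramps_are_improvers(self):
        series = {f"u{i}": np.linspace(0.2, 0.9, 15) for i in range(5)}
        users, pictures = _toy_cohort_frames(series)
        out, counts = classify_cohort_trends(users, pictures)
        assert counts["Improver"] == 5
        assert counts["Decliner"] == 0 and counts["NoTrend"] == 0

    def test_partition_of_eligible_actives(self):
        rng = np.random.default_rng(0)
        series = {f"u{i}": rng.uniform(0, 1, rng.integers(3, 40)) for i in range(50)}
        users, pictures = _toy_cohort_frames(series)
        out, counts = classify_cohort_trends(users, pictures)
        assert len(out) == 50
        assert sum(counts.values()) == 50

    def test_short_series_counted_as_no_trend(self):
        series = {"u0": [0.1, 0.9], "u1": np.linspace(0.1, 0.9, 10)}
        users, pictures = _toy_cohort_frames(series)
        out, counts = classify_cohort_trends(users, pictures)
        assert counts["NoTrend"] == 1 and counts["Improver"] == 1


class TestCompareImprovers:
    @staticmethod
    def _frames(values_a, values_b):
        n_a, n_b = len(values_a), len(values_b)
        users = pd.DataFrame(
            {
                "user_id": [f"u{i}" for i in range(n_a + n_b)],
                "n_valid_pictures": np.concatenate([values_a, values_b]),
                "usage_period_days": [10.0] * (n_a + n_b),
                "pictures_per_day": [1.0] * (n_a + n_b),
            }
        )
        trend = pd.DataFrame(
            {
                "user_id": users["user_id"],
                "classification": [TrendClass.IMPROVER] * n_a + [TrendClass.NO_TREND] * n_b,
            }
        )
        return trend, users

    def test_identical_groups_all_zero(self):
        trend, users = self._frames([10, 20, 30], [10, 20, 30])
        res = compare_improvers(trend, users)
        for r in res.values():
            assert r.statistic == pytest.approx(0.0)

    def test_shift_on_one_variable_only(self):
        trend, users = self._frames([15, 16, 17], [10, 11, 12])
        res = compare_improvers(trend, users)
        assert res["n_valid_pictures"].statistic > 4
        assert res["usage_period_days"].statistic == pytest.approx(0.0)
        assert res["pictures_per_day"].statistic == pytest.approx(0.0)

    def test_degenerate_group_fatal(self):
        trend, users = self._frames([10], [10, 20, 30])
        with pytest.raises(ValueError):
            compare_improvers(trend, users)
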