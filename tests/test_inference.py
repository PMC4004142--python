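"""The statistics core against hand computations and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dietcohort import (
    ProportionTable,
    anova_from_summary,
    anova_oneway,
    bonferroni_alpha,
    chi2_2x2,
    chi2_homogeneity,
    grid_proportion_scan,
    pooled_t,
    tukey_hsd_means,
    tukey_hsd_proportions,
)


def table(succ, tot):
    return ProportionTable(tuple(str(i) for i in range(len(succ))), tuple(succ), tuple(tot))


class TestChiSquare:
    def test_hand_computed_2x2_as_homogeneity(self):
        res = chi2_homogeneity(table([1, 3], [4, 4]))
        assert res.statistic == pytest.approx(2.0)
        assert res.df == (1,)

    def test_homogeneous_table_is_zero(self):
        assert chi2_homogeneity(table([10, 20], [100, 200])).statistic == pytest.approx(0.0)

    def test_closed_form_2x2(self):
        res = chi2_2x2(200, 800, 100, 900)
        assert res.statistic == pytest.approx(39.2157, abs=1e-3)

    def test_proportional_2x2_is_zero(self):
        assert chi2_2x2(10, 30, 20, 60).statistic == pytest.approx(0.0)

    def test_zero_margin_fatal(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)
        with pytest.raises(ValueError):
            chi2_homogeneity(table([0, 0], [5, 5]))

    @given(
        succ=st.lists(st.integers(1, 200), min_size=2, max_size=6),
        extra=st.lists(st.integers(1, 200), min_size=2, max_size=6),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_scipy_contingency(self, succ, extra):
        k = min(len(succ), len(extra))
        succ, fail = succ[:k], extra[:k]
        tot = [s + f for s, f in zip(succ, fail)]
        res = chi2_homogeneity(table(succ, tot))
        obs = np.array([succ, fail])
        expected = stats.chi2_contingency(obs, correction=False)
        assert res.statistic == pytest.approx(expected.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(expected.pvalue, rel=1e-9, abs=1e-300)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_closed_form_equals_homogeneity(self, a, b, c, d):
        closed = chi2_2x2(a, b, c, d)
        general = chi2_homogeneity(table([a, c], [a + b, c + d]))
        assert closed.statistic == pytest.approx(general.statistic, rel=1e-9, abs=1e-12)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_alpha(0.05, 35) == pytest.approx(0.0014285714285714286)
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_decisions_at_corrected_level_are_a_subset(self):
        rng = np.random.default_rng(0)
        p = rng.random(1000)
        for m in (2, 5, 35):
            assert np.all((p < bonferroni_alpha(0.05, m)) <= (p < 0.05))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestAnova:
    def test_hand_computed(self):
        res = anova_oneway([[0, 1], [2, 3]])
        assert res.statistic == pytest.approx(8.0)
        assert res.df == (1.0, 2.0)

    def test_identical_groups_give_zero_f(self):
        assert anova_oneway([[1, 2, 3], [1, 2, 3]]).statistic == pytest.approx(0.0)

    def test_summary_hand_computed(self):
        res = anova_from_summary([0, 2], [1, 1], [2, 2])
        assert res.statistic == pytest.approx(4.0)

    def test_all_equal_means_zero_f(self):
        assert anova_from_summary([3, 3, 3], [1, 2, 3], [5, 5, 5]).statistic == 0.0

    def test_zero_within_variance_signals_infinite_f(self):
        res = anova_oneway([[1, 1, 1], [2, 2, 2]])
        assert np.isinf(res.statistic) and res.p_value == 0.0

    @given(
        data=st.lists(
            st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=12),
            min_size=2,
            max_size=5,
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_raw_and_summary_forms_agree(self, data):
        raw = anova_oneway(data)
        summ = anova_from_summary(
            [np.mean(g) for g in data],
            [np.std(g, ddof=1) for g in data],
            [len(g) for g in data],
        )
        if np.isfinite(raw.statistic):
            assert summ.statistic == pytest.approx(raw.statistic, rel=1e-6, abs=1e-9)
        assert summ.df == raw.df

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            groups = [rng.normal(rng.normal(), 1 + rng.random(), rng.integers(3, 20)) for _ in range(3)]
            mine = anova_oneway(groups)
            ref = stats.f_oneway(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestPooledT:
    def test_hand_computed(self):
        res = pooled_t(0, 1, 2, 2, 1, 2)
        assert abs(res.statistic) == pytest.approx(2.0)
        assert res.df == (2.0,)

    def test_equal_means_zero(self):
        assert pooled_t(5, 1, 10, 5, 2, 12).statistic == pytest.approx(0.0)

    def test_antisymmetric_under_group_exchange(self):
        a = pooled_t(3.2, 1.1, 14, 1.9, 0.7, 9)
        b = pooled_t(1.9, 0.7, 9, 3.2, 1.1, 14)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_from_stats(self):
        ref = stats.ttest_ind_from_stats(3.2, 1.1, 14, 1.9, 0.7, 9, equal_var=True)
        mine = pooled_t(3.2, 1.1, 14, 1.9, 0.7, 9)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_signals(self):
        with pytest.raises(ValueError):
            pooled_t(0, 0, 5, 1, 0, 5)


class TestTukeyMeans:
    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mu, 1, 50) for mu in (0, 10, 20)]
        res = tukey_hsd_means(groups, ["a", "b", "c"])
        assert res.significant == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_identical_groups_nothing_significant(self):
        g = list(np.arange(10.0))
        res = tukey_hsd_means([g, g, g])
        assert res.significant == frozenset()

    def test_significant_set_grows_with_alpha(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(mu, 2, 25) for mu in (0.0, 0.9, 1.8, 5.0)]
        prev = frozenset()
        for alpha in (0.001, 0.01, 0.05, 0.2):
            sig = tukey_hsd_means(groups, alpha=alpha).significant
            assert prev <= sig
            prev = sig

    def test_p_values_match_scipy_tukey(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 1.5, n) for mu, n in ((0, 12), (1, 17), (2.5, 9))]
        mine = tukey_hsd_means(groups, ["0", "1", "2"])
        ref = stats.tukey_hsd(*groups)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mine.p_values[(str(i), str(j))] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-8
                )


class TestTukeyProportions:
    def test_equal_proportions_nothing_significant(self):
        res = tukey_hsd_proportions(table([10, 10, 10], [100, 100, 100]))
        assert res.significant == frozenset()

    def test_large_separated_proportions_all_significant(self):
        res = tukey_hsd_proportions(table([100, 500, 900], [1000, 1000, 1000]))
        assert len(res.significant) == 3

    def test_endpoint_proportions_handled(self):
        res = tukey_hsd_proportions(table([0, 50, 100], [100, 100, 100]))
        assert np.isfinite(list(res.q.values())).all()
        assert len(res.significant) == 3

    def test_two_group_direction_agrees_with_chi2_at_large_n(self):
        rng = np.random.default_rng(5)
        agree = 0
        total = 60
        for _ in range(total):
            n1, n2 = rng.integers(500, 3000, 2)
            p1, p2 = rng.uniform(0.1, 0.9, 2)
            s1, s2 = int(p1 * n1), int(p2 * n2)
            tk = tukey_hsd_proportions(table([s1, s2], [n1, n2]), alpha=0.05)
            ch = chi2_2x2(s1, n1 - s1, s2, n2 - s2)
            agree += (len(tk.significant) > 0) == (ch.p_value < 0.05)
        assert agree >= total - 3  # same decision except marginal cases


class TestGridScan:
    @staticmethod
    def uniform_grid(total):
        g = np.full((7, 5), total // 35, dtype=float)
        return g

    def test_identical_grids_all_no_difference(self):
        g = self.uniform_grid(3500)
        res = grid_proportion_scan(g, g * 3)
        assert (res.labels == "no_difference").all()

    def test_constructed_enriched_cell_detected(self):
        users = self.uniform_grid(0) + 800 / 34.0
        drops = self.uniform_grid(0) + 900 / 34.0
        users[2, 2] = 200.0  # 20% of 1000 users in one cell
        drops[2, 2] = 100.0  # 10% of 1000 dropouts
        users *= 1000 / users.sum()
        drops *= 1000 / drops.sum()
        res = grid_proportion_scan(users, drops)
        assert res.labels[2, 2] == "users_enriched"
        assert res.statistic[2, 2] == pytest.approx(39.2, abs=0.1)

    def test_symmetry_under_group_exchange(self):
        rng = np.random.default_rng(6)
        users = rng.multinomial(4000, np.full(35, 1 / 35)).reshape(7, 5).astype(float)
        drops = rng.multinomial(20000, np.full(35, 1 / 35)).reshape(7, 5).astype(float)
        users[1, 1] += 600
        a = grid_proportion_scan(users, drops)
        b = grid_proportion_scan(drops, users)
        swap = {"users_enriched": "dropouts_enriched", "dropouts_enriched": "users_enriched", "no_difference": "no_difference"}
        assert all(swap[x] == y for x, y in zip(a.labels.ravel(), b.labels.ravel()))
        np.testing.assert_allclose(a.statistic, b.statistic, rtol=1e-12)

    def test_empty_grid_fatal(self):
        with pytest.raises(ValueError):
            grid_proportion_scan(np.zeros((7, 5)), np.ones((7, 5)))
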