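"""Statistics core: proportion homogeneity, grid scans, ANOVA, Tukey, pooled t.

All chi-square statistics are plain Pearson sums without continuity
correction, which is what reproduces the published contingency-table
statistics of this kind of usage-log analysis. p-values are two-sided
throughout; summary-based forms use the sample (n-1) SD convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionTable",
    "chi2_homogeneity",
    "chi2_2x2",
    "bonferroni_alpha",
    "grid_proportion_scan",
    "GridScanResult",
    "anova_oneway",
    "anova_from_summary",
    "pooled_t",
    "tukey_hsd_means",
    "tukey_hsd_proportions",
    "TukeyResult",
]


@dataclass(frozen=True)
class ProportionTable:
    """k groups of successes/totals — one 2 x k contingency table."""

    labels: tuple[str, ...]
    successes: tuple[int, ...]
    totals: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least 2 groups")
        if len(self.successes) != k or len(self.totals) != k:
            raise ValueError("labels, successes and totals must have equal length")
        for s, t in zip(self.successes, self.totals):
            if t <= 0:
                raise ValueError("every group total must be positive")
            if not 0 <= s <= t:
                raise ValueError(f"successes {s} outside [0, total {t}]")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.successes, float) / np.asarray(self.totals, float)


def chi2_homogeneity(table: ProportionTable) -> TestResult:
    """Pearson chi-square test that k group proportions are equal.

    Statistic is sum (O-E)^2 / E over the 2 x k table of successes and
    failures, df = k-1, upper-tail p. No continuity correction.
    """
    succ = np.asarray(table.successes, float)
    tot = np.asarray(table.totals, float)
    obs = np.vstack([succ, tot - succ])
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    if (expected == 0).any():
        raise ValueError("expected cell count of zero (all successes or all failures)")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(table.labels) - 1
    return TestResult(statistic, (df,), float(stats.chi2.sf(statistic, df)), "chi2")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square for a 2 x 2 table [[a, b], [c, d]], closed form.

    Equals :func:`chi2_homogeneity` on the equivalent two-group proportion
    table: N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1, no correction.
    """
    a, b, c, d = (float(x) for x in (a, b, c, d))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    statistic = n * (a * d - b * c) ** 2 / margins
    return TestResult(statistic, (1,), float(stats.chi2.sf(statistic, 1)), "chi2")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison level alpha/m controlling the family-wise error over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


@dataclass(frozen=True)
class GridScanResult:
    """Per-cell verdicts of the registration-grid enrichment scan."""

    labels: np.ndarray       # (7, 5) strings: users_enriched | dropouts_enriched | no_difference
    statistic: np.ndarray    # (7, 5) chi-square values (NaN where undefined)
    p_value: np.ndarray      # (7, 5)
    alpha_adjusted: float


def grid_proportion_scan(
    users_bins: np.ndarray,
    dropouts_bins: np.ndarray,
    alpha: float = 0.05,
) -> GridScanResult:
    """Scan a weekday x daypart registration grid for adherence enrichment.

    For each of the 35 cells, a 2 x 2 chi-square compares (this cell vs all
    other cells) x (Users vs Dropouts). A cell is ``users_enriched`` when
    significant at the Bonferroni-adjusted level alpha/35 with a larger
    share of Users registering in that cell than of Dropouts;
    ``dropouts_enriched`` in the opposite direction; else ``no_difference``.
    """
    users = np.asarray(users_bins, dtype=float)
    drops = np.asarray(dropouts_bins, dtype=float)
    if users.shape != drops.shape:
        raise ValueError("the two grids must have identical shape")
    n_users, n_drops = users.sum(), drops.sum()
    if n_users <= 0 or n_drops <= 0:
        raise ValueError("both groups must have a positive grid total")

    m = users.size
    alpha_adj = bonferroni_alpha(alpha, m)
    labels = np.full(users.shape, "no_difference", dtype=object)
    chi = np.full(users.shape, np.nan)
    pvals = np.full(users.shape, np.nan)
    for idx in np.ndindex(users.shape):
        a, c = users[idx], drops[idx]
        b, d = n_users - a, n_drops - c
        if (a + c) == 0 or (b + d) == 0:
            continue
        res = chi2_2x2(a, b, c, d)
        chi[idx] = res.statistic
        pvals[idx] = res.p_value
        if res.p_value < alpha_adj:
            labels[idx] = (
                "users_enriched" if a / n_users > c / n_drops else "dropouts_enriched"
            )
    return GridScanResult(labels, chi, pvals, alpha_adj)


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA on raw values.

    F = MS_between / MS_within with df (k-1, n-k). Zero within-group
    variance with separated means yields an infinite F (p = 0); fully
    degenerate identical data yields F = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 1).any() or ns.sum() <= k:
        raise ValueError("need total n > k with every group non-empty")
    n = ns.sum()
    means = np.array([a.mean() for a in arrays])
    grand = sum(a.sum() for a in arrays) / n
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    return _f_result(ssb, ssw, k, n)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> TestResult:
    """One-way ANOVA reconstructed from per-group means, sample SDs, and sizes."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("SDs must be nonnegative")
    n = ns.sum()
    grand = (ns * means).sum() / n
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    return _f_result(ssb, ssw, len(means), n)


def _f_result(ssb: float, ssw: float, k: int, n: float) -> TestResult:
    df1, df2 = k - 1, n - k
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0:
        statistic = 0.0 if msb == 0 else float("inf")
        p = 1.0 if msb == 0 else 0.0
    else:
        statistic = msb / msw
        p = float(stats.f.sf(statistic, df1, df2))
    return TestResult(float(statistic), (float(df1), float(df2)), p, "F")


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-sample pooled-variance Student t from group summaries.

    df = n1 + n2 - 2, two-sided p. SDs use the sample (n-1) convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, (float(df),), 1.0, "t")
        raise ValueError("degenerate: both group variances are zero with distinct means")
    statistic = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * float(stats.t.sf(abs(statistic), df))
    return TestResult(float(statistic), (float(df),), p, "t")


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise studentized-range comparisons at family-wise level alpha."""

    labels: tuple[str, ...]
    q: dict = field(default_factory=dict)         # (label_i, label_j) -> q statistic
    p_values: dict = field(default_factory=dict)  # (label_i, label_j) -> p
    significant: frozenset = frozenset()          # pairs with p < alpha
    alpha: float = 0.05


def _pairwise_q(
    labels: Sequence[str],
    centers: np.ndarray,
    half_sq_se: np.ndarray,
    k: int,
    df: float,
    alpha: float,
) -> TukeyResult:
    q, pv, sig = {}, {}, []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(half_sq_se[i] + half_sq_se[j])
            qij = abs(centers[i] - centers[j]) / se
            pij = float(stats.studentized_range.sf(qij, k, df))
            pair = (labels[i], labels[j])
            q[pair] = float(qij)
            pv[pair] = pij
            if pij < alpha:
                sig.append(pair)
    return TukeyResult(tuple(labels), q, pv, frozenset(sig), alpha)


def tukey_hsd_means(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey(-Kramer) HSD comparison of group means.

    Uses MS_within from the one-way ANOVA and the studentized range with
    df = n - k; unequal group sizes use the Kramer average-variance form.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if labels is None:
        labels = [str(i + 1) for i in range(k)]
    anova = anova_oneway(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    n = ns.sum()
    msw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays)) / (n - k)
    if msw == 0:
        msw = np.finfo(float).tiny  # all-identical groups: q = 0 or inf
    centers = np.array([a.mean() for a in arrays])
    half_sq_se = msw / (2.0 * ns)
    return _pairwise_q(list(labels), centers, half_sq_se, k, n - k, alpha)


def tukey_hsd_proportions(table: ProportionTable, alpha: float = 0.05) -> TukeyResult:
    """Tukey-type multiple comparison among proportions (arcsine transform).

    Each proportion is transformed as phi = arcsin(sqrt(p)), whose large-n
    variance 1/(4n) is free of p; pairs are then compared with the
    studentized range at infinite df (Zar's procedure). Proportions of
    exactly 0 or 1 use the standard endpoint adjustment
    arcsin(sqrt(1/(4n))) from the corresponding end of the scale.
    """
    p = table.proportions
    n = np.asarray(table.totals, dtype=float)
    phi = np.arcsin(np.sqrt(p))
    adj = np.arcsin(np.sqrt(1.0 / (4.0 * n)))
    phi = np.where(p == 0, adj, phi)
    phi = np.where(p == 1, np.pi / 2 - adj, phi)
    half_sq_se = 1.0 / (8.0 * n)
    return _pairwise_q(list(table.labels), phi, half_sq_se, len(p), np.inf, alpha)
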