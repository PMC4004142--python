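"""Per-user healthiness-trend detection among Active users.

For each eligible Active user, the average peer rating of each picture is
regressed on the picture index 1..N (ordered list of pictures, not real
time). A significant positive slope marks an "Improver", a significant
negative slope a "Decliner"; everyone else shows no trend.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import pooled_t
from .model import Adherence, TestResult, TrendClass, TrendResult

logger = logging.getLogger(__name__)

__all__ = [
    "fit_user_trend",
    "classify_cohort_trends",
    "compare_improvers",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Fewer rated pictures than the slope t-test requires (minimum 3)."""


def fit_user_trend(ratings: Sequence[float], alpha: float = 0.05) -> TrendResult:
    """OLS trend of one user's ordered per-picture ratings.

    The predictor is the picture index 1..N; slope = Sxy / Sxx in rating
    units per picture. The slope's two-sided t-test (df = N-2) decides the
    class at level ``alpha``. A perfectly fit nonconstant line has zero
    residual variance and is treated as p = 0 with the sign of the slope.
    """
    y = np.asarray(ratings, dtype=float)
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 ratings, got {n}")
    x = np.arange(1, n + 1, dtype=float)
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - y.mean())).sum()
    slope = sxy / sxx
    resid = y - y.mean() - slope * (x - xbar)
    sse = float((resid**2).sum())
    if sse <= 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        from scipy import stats

        se = np.sqrt(sse / (n - 2) / sxx)
        p = 2 * float(stats.t.sf(abs(slope) / se, n - 2))
    if slope > 0 and p < alpha:
        cls = TrendClass.IMPROVER
    elif slope < 0 and p < alpha:
        cls = TrendClass.DECLINER
    else:
        cls = TrendClass.NO_TREND
    return TrendResult(float(slope), p, n, cls)


def classify_cohort_trends(
    user_summaries: pd.DataFrame,
    picture_summaries: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fit a healthiness trend for every eligible Active user.

    Eligible users are Actives with a valid picture among their first two
    (``first_valid_picture_id`` present). The series is the chronologically
    ordered average peer ratings of the user's counted pictures; pictures
    without any peer rating are skipped, the remaining ratings keeping
    their relative order as indices 1..N. Users with fewer than 3 rated
    pictures cannot support the t-test and are recorded as NoTrend.

    Returns a per-user frame (user_id, slope, p_value, n_points,
    classification) and the class counts.
    """
    us = user_summaries
    eligible = us[(us["adherence"] == Adherence.ACTIVE) & us["first_valid_picture_id"].notna()]
    ps = picture_summaries
    counted = ps[ps.get("counted", pd.Series(True, index=ps.index))].copy()
    counted = counted[counted["avg_peer_rating"].notna()]
    counted = counted.sort_values(["user_id", "ordinal"], kind="mergesort")
    series = {
        uid: grp["avg_peer_rating"].to_numpy()
        for uid, grp in counted.groupby("user_id", sort=False)
    }

    rows = []
    for uid in eligible["user_id"]:
        y = series.get(uid, np.empty(0))
        if len(y) < 3:
            rows.append((uid, 0.0, 1.0, len(y), TrendClass.NO_TREND))
            continue
        r = fit_user_trend(y, alpha=alpha)
        rows.append((uid, r.slope, r.p_value, r.n_points, r.classification))
    out = pd.DataFrame(
        rows, columns=["user_id", "slope", "p_value", "n_points", "classification"]
    )
    counts = {cls.value: int((out["classification"] == cls).sum()) for cls in TrendClass}
    logger.info(
        "trend classification of %d eligible Actives: %s", len(out), counts
    )
    return out, counts


def compare_improvers(
    trend_table: pd.DataFrame, user_summaries: pd.DataFrame
) -> dict[str, TestResult]:
    """Pooled t-tests of Improvers vs all other eligible Actives.

    Compares usage activity on three variables: adjusted number of
    pictures, usage period in days, and pictures per day.
    """
    merged = trend_table.merge(user_summaries, on="user_id", how="left")
    is_imp = (merged["classification"] == TrendClass.IMPROVER).to_numpy()
    if is_imp.sum() < 2 or (~is_imp).sum() < 2:
        raise ValueError("need at least 2 Improvers and 2 other Actives")
    results = {}
    for var in ("n_valid_pictures", "usage_period_days", "pictures_per_day"):
        a = merged.loc[is_imp, var].to_numpy(dtype=float)
        b = merged.loc[~is_imp, var].to_numpy(dtype=float)
        results[var] = pooled_t(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
    return results
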