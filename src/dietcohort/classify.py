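"""Adherence levels, dietary-preference categories, registration-time bins."""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np
import pandas as pd

from .model import Adherence, DayInterval, DietCategory, DAY_INTERVALS, INTERVAL_START_HOURS

__all__ = [
    "classify_adherence",
    "classify_adherence_arrays",
    "categorize_diet",
    "bin_registration",
    "bin_registration_series",
    "pictures_per_day",
    "ACTIVE_MIN_PICTURES",
    "ACTIVE_MIN_PERIOD_DAYS",
]

# An Active user took at least 10 valid pictures over a usage period of at
# least one week. The week bound is inclusive (>= 7.0 days) and configurable.
ACTIVE_MIN_PICTURES = 10
ACTIVE_MIN_PERIOD_DAYS = 7.0

# Canonical onboarding answer options, lowercased. "Strict" diets restrict
# whole food groups; any other non-"everything" answer (including free text)
# is "Other". Precedence: Strict > Other > Everything > NotDefined.
STRICT_OPTIONS = frozenset(
    {
        "low carb, no carb, or paleo",
        "low carbs, no carbs, or paleo",
        "low fat",
        "vegan/vegetarian",
        "vegan or vegetarian",
    }
)
EVERYTHING_OPTION = "i eat everything!"


def classify_adherence(
    n_valid_pictures: int,
    usage_period_days: float,
    min_pictures: int = ACTIVE_MIN_PICTURES,
    min_period_days: float = ACTIVE_MIN_PERIOD_DAYS,
) -> Adherence:
    """Adherence level from adjusted picture count and usage period.

    NonUser: 0 valid pictures. NonActive: exactly 1. Active: at least
    ``min_pictures`` and a period of at least ``min_period_days``.
    SemiActive: everything else (>= 2 pictures).
    """
    if n_valid_pictures < 0 or usage_period_days < 0:
        raise ValueError("picture count and usage period must be nonnegative")
    if n_valid_pictures == 0:
        return Adherence.NON_USER
    if n_valid_pictures == 1:
        return Adherence.NON_ACTIVE
    if n_valid_pictures >= min_pictures and usage_period_days >= min_period_days:
        return Adherence.ACTIVE
    return Adherence.SEMI_ACTIVE


def classify_adherence_arrays(
    n_valid_pictures: np.ndarray,
    usage_period_days: np.ndarray,
    min_pictures: int = ACTIVE_MIN_PICTURES,
    min_period_days: float = ACTIVE_MIN_PERIOD_DAYS,
) -> np.ndarray:
    """Vectorized :func:`classify_adherence`; returns an object array of Adherence."""
    n = np.asarray(n_valid_pictures)
    p = np.asarray(usage_period_days, dtype=float)
    if (n < 0).any() or (p < 0).any():
        raise ValueError("picture count and usage period must be nonnegative")
    out = np.empty(n.shape, dtype=object)
    out[:] = Adherence.SEMI_ACTIVE  # np.full would str-coerce the enum member
    out[(n >= min_pictures) & (p >= min_period_days)] = Adherence.ACTIVE
    out[n == 1] = Adherence.NON_ACTIVE
    out[n == 0] = Adherence.NON_USER
    return out


def categorize_diet(responses: Iterable[str]) -> DietCategory:
    """Dietary-preference category from the raw answer strings.

    Matching is case-insensitive on the canonical option strings; order and
    duplication of responses are irrelevant. A user with any strict option
    is Strict; otherwise any answer besides "I eat everything!" makes them
    Other; otherwise Everything; no answers at all means NotDefined.
    """
    normalized = {r.strip().lower() for r in responses if r.strip()}
    if not normalized:
        return DietCategory.NOT_DEFINED
    if normalized & STRICT_OPTIONS:
        return DietCategory.STRICT
    if normalized - {EVERYTHING_OPTION}:
        return DietCategory.OTHER
    return DietCategory.EVERYTHING


def bin_registration(registered_at: _dt.datetime | pd.Timestamp) -> tuple[int, DayInterval]:
    """Weekday (0=Sunday .. 6=Saturday) and daypart of first app use.

    Dayparts by hour, half-open: night [0,5), morning [5,10), daytime
    [10,15), late afternoon [15,19), evening [19,24). Raises ValueError for
    an absent registration time (such users are unbinnable and excluded
    from registration-time analyses).
    """
    if registered_at is None or pd.isna(registered_at):
        raise ValueError("registration time absent: user is unbinnable")
    ts = pd.Timestamp(registered_at)
    weekday = (ts.weekday() + 1) % 7  # pandas Monday=0 -> Sunday=0
    idx = int(np.searchsorted(INTERVAL_START_HOURS, ts.hour, side="right") - 1)
    return weekday, DAY_INTERVALS[idx]


def bin_registration_series(registered_at: pd.Series) -> pd.DataFrame:
    """Vectorized registration binning; NaT rows yield NA in both columns."""
    ts = pd.to_datetime(registered_at)
    ok = ts.notna()
    weekday = pd.Series(pd.NA, index=ts.index, dtype="Int64")
    weekday[ok] = (ts[ok].dt.weekday + 1) % 7
    idx = np.searchsorted(INTERVAL_START_HOURS, ts[ok].dt.hour.to_numpy(), side="right") - 1
    interval = pd.Series(pd.NA, index=ts.index, dtype=object)
    interval[ok] = np.asarray(DAY_INTERVALS, dtype=object)[idx]
    return pd.DataFrame({"reg_weekday": weekday, "reg_interval": interval})


def pictures_per_day(n_valid_pictures: float, usage_period_days: float) -> float:
    """Self-monitoring frequency; periods under a day count as one day."""
    return n_valid_pictures / max(usage_period_days, 1.0)
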