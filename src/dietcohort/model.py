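"""Domain types and CSV readers/writers for app usage-log cohorts.

A cohort is five flat event-log tables describing a photographic dietary
self-monitoring app: users, pictures (self-monitoring entries), crowdsourced
peer ratings on a 0-1 "fat"-to-"fit" healthiness scale, likes and comments.
Timestamps are local civil time as recorded by the user's phone; the stored
UTC offset is metadata only and is never applied as a conversion.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Adherence",
    "DietCategory",
    "DayInterval",
    "TestResult",
    "TrendResult",
    "Cohort",
    "CohortDataError",
    "CohortIntegrityError",
    "load_cohort",
    "write_cohort",
    "split_diet_responses",
]


class Adherence(str, enum.Enum):
    """Adherence level, from frequency and duration of self-monitoring.

    NonUser: no valid pictures. NonActive: exactly one valid picture.
    Active: at least 10 valid pictures spanning at least one week.
    SemiActive: every other user with at least two valid pictures.
    NonUser and NonActive together are "Dropouts"; the rest are "Users".
    """

    NON_USER = "NonUser"
    NON_ACTIVE = "NonActive"
    SEMI_ACTIVE = "SemiActive"
    ACTIVE = "Active"


class DietCategory(str, enum.Enum):
    """Dietary-preference category from the "How do you eat?" onboarding question."""

    NOT_DEFINED = "NotDefined"
    EVERYTHING = "Everything"
    STRICT = "Strict"
    OTHER = "Other"


class DayInterval(str, enum.Enum):
    """Time-of-day interval of first app use (hour, half-open on the right)."""

    NIGHT = "night"                  # [0, 5)
    MORNING = "morning"              # [5, 10)
    DAYTIME = "daytime"              # [10, 15)
    LATE_AFTERNOON = "late_afternoon"  # [15, 19)
    EVENING = "evening"              # [19, 24)


# Fixed, analysis-wide ordering of the five dayparts (column order of the
# 7 x 5 registration grid; rows are weekdays with 0 = Sunday).
DAY_INTERVALS: tuple[DayInterval, ...] = (
    DayInterval.NIGHT,
    DayInterval.MORNING,
    DayInterval.DAYTIME,
    DayInterval.LATE_AFTERNOON,
    DayInterval.EVENING,
)

INTERVAL_START_HOURS = (0, 5, 10, 15, 19)
INTERVAL_END_HOURS = (5, 10, 15, 19, 24)


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: tuple[float, ...]
    p_value: float
    kind: str  # "chi2" | "F" | "t"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError(f"degrees of freedom must be positive, got {self.df}")


class TrendClass(str, enum.Enum):
    """Per-user linear-trend verdict on healthiness ratings over picture index."""

    IMPROVER = "Improver"
    DECLINER = "Decliner"
    NO_TREND = "NoTrend"


@dataclass(frozen=True)
class TrendResult:
    """OLS slope of average peer rating on picture index, with slope t-test."""

    slope: float
    p_value: float
    n_points: int
    classification: TrendClass

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a trend needs at least 2 points")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


class CohortDataError(ValueError):
    """A cohort table is missing, malformed, or violates a field invariant."""


class CohortIntegrityError(CohortDataError):
    """A foreign key does not resolve (dangling picture or user reference)."""


USERS_COLUMNS = ["user_id", "registered_at", "tz_offset_hours", "diet_responses"]
PICTURES_COLUMNS = ["picture_id", "user_id", "taken_at", "has_image", "self_rating", "description"]
RATINGS_COLUMNS = ["rating_id", "picture_id", "rater_id", "value", "rated_at"]
LIKES_COLUMNS = ["picture_id", "peer_id"]
COMMENTS_COLUMNS = ["picture_id", "peer_id", "text"]

_FILES = {
    "users": USERS_COLUMNS,
    "pictures": PICTURES_COLUMNS,
    "ratings": RATINGS_COLUMNS,
    "likes": LIKES_COLUMNS,
    "comments": COMMENTS_COLUMNS,
}

_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass
class Cohort:
    """The five event-log tables of one app cohort.

    ``meta`` carries non-serialized annotations (e.g. ground-truth archetypes
    of a synthetic cohort); it is ignored by :func:`write_cohort`.
    """

    users: pd.DataFrame
    pictures: pd.DataFrame
    ratings: pd.DataFrame
    likes: pd.DataFrame
    comments: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_pictures(self) -> int:
        return len(self.pictures)

    def validate(self) -> None:
        """Check uniqueness, value ranges, and referential integrity."""
        for name, cols in _FILES.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise CohortDataError(f"{name} table lacks columns {missing}")
        if self.users["user_id"].duplicated().any():
            dup = self.users.loc[self.users["user_id"].duplicated(), "user_id"].tolist()
            raise CohortDataError(f"duplicate user_id values: {dup[:5]}")
        if self.pictures["picture_id"].duplicated().any():
            dup = self.pictures.loc[self.pictures["picture_id"].duplicated(), "picture_id"].tolist()
            raise CohortDataError(f"duplicate picture_id values: {dup[:5]}")
        tz = self.users["tz_offset_hours"].dropna()
        if len(tz) and ((tz < -12) | (tz > 14)).any():
            raise CohortDataError("tz_offset_hours outside [-12, +14]")
        for col, frame, name in [
            ("self_rating", self.pictures, "pictures"),
            ("value", self.ratings, "ratings"),
        ]:
            vals = frame[col].dropna()
            if len(vals) and ((vals < 0) | (vals > 1)).any():
                raise CohortDataError(f"{name}.{col} outside [0, 1]")
        self._check_references()

    def _check_references(self) -> None:
        known_users = set(self.users["user_id"])
        bad = set(self.pictures["user_id"]) - known_users
        if bad:
            raise CohortIntegrityError(
                f"pictures reference unknown user_id(s): {sorted(bad)[:10]}"
            )
        known_pics = set(self.pictures["picture_id"])
        for name in ("ratings", "likes", "comments"):
            bad = set(getattr(self, name)["picture_id"]) - known_pics
            if bad:
                raise CohortIntegrityError(
                    f"{name} reference unknown picture_id(s): {sorted(bad)[:10]}"
                )
        for name, col in (("ratings", "rater_id"), ("likes", "peer_id"), ("comments", "peer_id")):
            bad = set(getattr(self, name)[col]) - known_users
            if bad:
                raise CohortIntegrityError(
                    f"{name}.{col} references unknown user_id(s): {sorted(bad)[:10]}"
                )


def split_diet_responses(serialized: str | float | None) -> list[str]:
    """Decode the semicolon-delimited diet_responses field (empty string = none)."""
    if serialized is None or (isinstance(serialized, float) and np.isnan(serialized)):
        return []
    s = str(serialized)
    return [part for part in s.split(";") if part != ""]


def _parse_floats(series: pd.Series, table: str, column: str) -> pd.Series:
    """Exact (round-trip) float parsing; blank means absent."""
    raw = series.fillna("").astype(str).to_numpy()
    out = np.full(len(raw), np.nan)
    present = raw != ""
    try:
        out[present] = np.asarray(raw[present], dtype=float)
    except ValueError as exc:
        raise CohortDataError(f"{table}.csv: malformed number in {column}: {exc}") from None
    return pd.Series(out, index=series.index)


def _parse_times(series: pd.Series, table: str, column: str, required: bool) -> pd.Series:
    raw = series.fillna("").astype(str)
    parsed = pd.to_datetime(raw.where(raw != "", None), format="ISO8601", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortDataError(
            f"{table}.csv row {row + 2}: malformed timestamp {raw.iloc[row]!r} in {column}"
        )
    if required and (raw == "").any():
        row = int(np.flatnonzero((raw == "").to_numpy())[0])
        raise CohortDataError(f"{table}.csv row {row + 2}: missing required timestamp {column}")
    return parsed


def load_cohort(directory: str | Path) -> Cohort:
    """Load the five cohort tables from ``directory`` and validate them.

    Raises :class:`CohortDataError` naming the file for a missing table, the
    row for a malformed timestamp, and the offending ids for a dangling
    foreign key. Row counts are reported via logging.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in _FILES.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise CohortDataError(f"missing cohort file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortDataError(f"{path} lacks columns {missing}")
        frames[name] = df[cols].copy()
        logger.info("loaded %s: %d rows", path.name, len(df))

    users = frames["users"]
    users["registered_at"] = _parse_times(users["registered_at"], "users", "registered_at", False)
    users["tz_offset_hours"] = pd.to_numeric(
        users["tz_offset_hours"].replace("", None), errors="raise"
    ).astype("Int64")

    pics = frames["pictures"]
    pics["taken_at"] = _parse_times(pics["taken_at"], "pictures", "taken_at", True)
    pics["has_image"] = pics["has_image"].astype(int).astype(bool)
    pics["self_rating"] = _parse_floats(pics["self_rating"], "pictures", "self_rating")

    ratings = frames["ratings"]
    ratings["value"] = _parse_floats(ratings["value"], "ratings", "value")
    ratings["rated_at"] = _parse_times(ratings["rated_at"], "ratings", "rated_at", False)

    cohort = Cohort(users, pics, ratings, frames["likes"], frames["comments"])
    cohort.validate()
    return cohort


def _format_times(series: pd.Series) -> pd.Series:
    if not pd.api.types.is_datetime64_any_dtype(series):
        series = pd.to_datetime(series)  # e.g. empty object column
    out = series.dt.strftime(_TIME_FORMAT)
    return out.fillna("")


def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write the cohort to ``directory`` in the canonical CSV schemas.

    Rows are emitted in deterministic id order, so writing the same cohort
    twice yields byte-identical files. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    users = cohort.users.sort_values("user_id", kind="mergesort").copy()
    users["registered_at"] = _format_times(users["registered_at"])
    users["tz_offset_hours"] = users["tz_offset_hours"].astype(object).where(
        users["tz_offset_hours"].notna(), ""
    )

    pics = cohort.pictures.sort_values("picture_id", kind="mergesort").copy()
    pics["taken_at"] = _format_times(pics["taken_at"])
    pics["has_image"] = pics["has_image"].astype(int)
    pics["self_rating"] = pics["self_rating"].astype(object).where(pics["self_rating"].notna(), "")

    ratings = cohort.ratings.sort_values("rating_id", kind="mergesort").copy()
    ratings["rated_at"] = _format_times(ratings["rated_at"])

    likes = cohort.likes.sort_values(["picture_id", "peer_id"], kind="mergesort")
    comments = cohort.comments.sort_values(["picture_id", "peer_id", "text"], kind="mergesort")

    written = []
    for name, df, cols in [
        ("users", users, USERS_COLUMNS),
        ("pictures", pics, PICTURES_COLUMNS),
        ("ratings", ratings, RATINGS_COLUMNS),
        ("likes", likes, LIKES_COLUMNS),
        ("comments", comments, COMMENTS_COLUMNS),
    ]:
        path = directory / f"{name}.csv"
        df[cols].to_csv(path, index=False, lineterminator="\n")
        written.append(path)
        logger.info("wrote %s: %d rows", path.name, len(df))
    return written
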