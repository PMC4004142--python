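"""Synthetic usage-log cohorts with the structure the analysis assumes.

The original event logs are proprietary, so every downstream stage is
exercised on generated cohorts instead. Users are drawn from adherence
*archetypes* (NonUser, NonActive, SemiActive, Active, plus Active variants
with a built-in positive or negative healthiness trend); each archetype
fixes a picture-count law, a usage-period law, and engagement rates. Peer
ratings for a picture are realized as individual values whose empirical
mean exactly equals the intended target
``clip(baseline + slope * (ordinal - 1) + noise, 0, 1)``, because the
downstream analyses consume only the per-picture mean and count.

Default rates and moments mirror the published summaries of a large
commercial food-photography app cohort (picture counts ~4 (SD ~4) for
semi-active and ~59 (SD ~100) for active users, ~19 crowd ratings per
picture, ~3% empty pictures, ~1.5% missing registration times); the
distributional *forms* (shifted negative-binomial counts, exponential
periods) are modelling conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model import Adherence, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "Law",
    "ArchetypeParams",
    "CohortConfig",
    "ConfigError",
    "generate_cohort",
    "expected_class_counts",
    "ARCHETYPES",
    "ARCHETYPE_ADHERENCE",
]

ARCHETYPES = (
    "NonUser",
    "NonActive",
    "SemiActive",
    "Active",
    "ActiveImprover",
    "ActiveDecliner",
)

ARCHETYPE_ADHERENCE: Mapping[str, Adherence] = {
    "NonUser": Adherence.NON_USER,
    "NonActive": Adherence.NON_ACTIVE,
    "SemiActive": Adherence.SEMI_ACTIVE,
    "Active": Adherence.ACTIVE,
    "ActiveImprover": Adherence.ACTIVE,
    "ActiveDecliner": Adherence.ACTIVE,
}

_ACTIVE_LIKE = ("Active", "ActiveImprover", "ActiveDecliner")


class ConfigError(ValueError):
    """The cohort configuration is invalid or infeasible."""


@dataclass(frozen=True)
class Law:
    """A small family of univariate sampling laws.

    kinds: ``constant`` (a), ``uniform_int`` (a..b inclusive), ``poisson``
    (mean a), ``negbin`` (mean a, dispersion b; variance a + a^2/b),
    ``exponential`` (scale a), ``normal`` (mean a, sd b). ``offset`` is
    added after sampling.
    """

    kind: str
    a: float = 0.0
    b: float | None = None
    offset: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            out = np.full(size, float(self.a))
        elif self.kind == "uniform_int":
            out = rng.integers(int(self.a), int(self.b) + 1, size).astype(float)
        elif self.kind == "poisson":
            out = rng.poisson(self.a, size).astype(float)
        elif self.kind == "negbin":
            r = float(self.b)
            p = r / (r + float(self.a))
            out = rng.negative_binomial(r, p, size).astype(float)
        elif self.kind == "exponential":
            out = rng.exponential(self.a, size)
        elif self.kind == "normal":
            out = rng.normal(self.a, self.b, size)
        else:
            raise ConfigError(f"unknown law kind {self.kind!r}")
        return out + self.offset

    @property
    def support_min(self) -> float:
        if self.kind == "constant":
            return self.a + self.offset
        if self.kind == "uniform_int":
            return self.a + self.offset
        if self.kind in ("poisson", "negbin", "exponential"):
            return self.offset
        return -np.inf

    @property
    def support_max(self) -> float:
        if self.kind == "constant":
            return self.a + self.offset
        if self.kind == "uniform_int":
            return float(self.b) + self.offset
        return np.inf

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "a": self.a}
        if self.b is not None:
            d["b"] = self.b
        if self.offset:
            d["offset"] = self.offset
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Law":
        return cls(d["kind"], d.get("a", 0.0), d.get("b"), d.get("offset", 0.0))


@dataclass(frozen=True)
class ArchetypeParams:
    """Per-archetype usage behaviour."""

    picture_count: Law
    usage_period: Law          # days between first and last picture
    trend_slope: float = 0.0   # rating units per picture index
    p_description: float = 0.5
    description_length: Law = Law("normal", 26.0, 18.0)
    p_like: float = 0.1
    p_comment: float = 0.04


# Table-2-style onboarding answers with single-response weights (percent);
# the empty string means the question was skipped.
DEFAULT_DIET_WEIGHTS: dict[str, float] = {
    "": 42.22,
    "I eat everything!": 46.33,
    "Low fat": 4.10,
    "Low carbs, no carbs, or paleo": 3.77,
    "Vegan or vegetarian": 3.28,
    "Complex carb diet": 1.26,
    "Other": 1.28,
    "Gluten free": 0.12,
    "None of the above": 0.90,
}

# Mostly Anglo-American users with a European minority.
DEFAULT_TZ_WEIGHTS: dict[int, float] = {
    -8: 0.171, -7: 0.171, -6: 0.171, -5: 0.171,
    0: 0.031, 1: 0.031, 2: 0.031, 3: 0.031,
    -4: 0.05, -9: 0.025, -10: 0.016, 5: 0.02, 8: 0.02, 9: 0.03, 10: 0.031,
}


def _default_archetypes() -> dict[str, ArchetypeParams]:
    return {
        "NonUser": ArchetypeParams(
            picture_count=Law("constant", 0),
            usage_period=Law("constant", 0),
            p_description=0.18,
            description_length=Law("normal", 20.1, 15.8),
            p_like=0.06,
            p_comment=0.02,
        ),
        "NonActive": ArchetypeParams(
            picture_count=Law("constant", 1),
            usage_period=Law("constant", 0),
            p_description=0.18,
            description_length=Law("normal", 20.1, 15.8),
            p_like=0.06,
            p_comment=0.02,
        ),
        "SemiActive": ArchetypeParams(
            picture_count=Law("uniform_int", 2, 9),
            usage_period=Law("exponential", 9.3),
            p_description=0.33,
            description_length=Law("normal", 23.4, 17.5),
            p_like=0.09,
            p_comment=0.05,
        ),
        "Active": ArchetypeParams(
            # >= 12 so the validity rule (at most 2 exclusions) cannot push
            # an intended Active below the 10-picture bound
            picture_count=Law("negbin", 47.0, 0.25, offset=12),
            usage_period=Law("exponential", 39.6, offset=7.0),
            p_description=0.53,
            description_length=Law("normal", 26.8, 19.1),
            p_like=0.13,
            p_comment=0.10,
        ),
        "ActiveImprover": ArchetypeParams(
            picture_count=Law("uniform_int", 30, 100),
            usage_period=Law("exponential", 40.0, offset=7.0),
            trend_slope=0.005,
            p_description=0.53,
            description_length=Law("normal", 26.8, 19.1),
            p_like=0.13,
            p_comment=0.10,
        ),
        "ActiveDecliner": ArchetypeParams(
            picture_count=Law("uniform_int", 30, 100),
            usage_period=Law("exponential", 40.0, offset=7.0),
            trend_slope=-0.005,
            p_description=0.53,
            description_length=Law("normal", 26.8, 19.1),
            p_like=0.13,
            p_comment=0.10,
        ),
    }


def _uniform_grid() -> np.ndarray:
    return np.full((7, 5), 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Everything :func:`generate_cohort` needs, reproducible from ``seed``."""

    n_per_archetype: dict[str, int] = field(
        default_factory=lambda: {"NonUser": 50, "NonActive": 30, "SemiActive": 15, "Active": 5}
    )
    archetypes: dict[str, ArchetypeParams] = field(default_factory=_default_archetypes)
    rating_count: Law = Law("poisson", 19.0)
    baseline_rating: Law = Law("normal", 0.52, 0.12)
    rating_noise_sd: float = 0.15
    self_rating_noise_sd: float = 0.10
    p_self_rating: float = 0.93
    p_empty_picture: float = 0.03
    p_test_first_picture: float = 0.04
    p_missing_registration: float = 0.0149
    p_second_diet_response: float = 0.02
    registration_grid: np.ndarray = field(default_factory=_uniform_grid)
    diet_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DIET_WEIGHTS))
    tz_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TZ_WEIGHTS))
    start_sunday: str = "2011-10-16"  # first Sunday of the study window
    n_weeks: int = 23
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_empty_picture": self.p_empty_picture,
            "p_test_first_picture": self.p_test_first_picture,
            "p_self_rating": self.p_self_rating,
            "p_missing_registration": self.p_missing_registration,
            "p_second_diet_response": self.p_second_diet_response,
        }
        for arc, params in self.archetypes.items():
            probs[f"{arc}.p_description"] = params.p_description
            probs[f"{arc}.p_like"] = params.p_like
            probs[f"{arc}.p_comment"] = params.p_comment
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        grid = np.asarray(self.registration_grid, dtype=float)
        if grid.shape != (7, 5) or (grid < 0).any() or grid.sum() <= 0:
            raise ConfigError("registration_grid must be a nonnegative 7x5 weight grid")
        for arc, n in self.n_per_archetype.items():
            if arc not in ARCHETYPES:
                raise ConfigError(f"unknown archetype {arc!r}")
            if n < 0:
                raise ConfigError(f"negative count for archetype {arc!r}")
            if n > 0 and arc not in self.archetypes:
                raise ConfigError(f"no parameters for archetype {arc!r}")
        for arc in _ACTIVE_LIKE:
            params = self.archetypes.get(arc)
            if params is None or self.n_per_archetype.get(arc, 0) == 0:
                continue
            if params.picture_count.support_max < 10:
                raise ConfigError(
                    f"infeasible: {arc} picture-count law is bounded above by "
                    f"{params.picture_count.support_max:g} < 10, so no draw can "
                    "reach the Active picture bound"
                )
            if params.usage_period.support_max < 7:
                raise ConfigError(
                    f"infeasible: {arc} usage-period law is bounded above by "
                    f"{params.usage_period.support_max:g} < 7 days"
                )
        if self.n_per_archetype.get("ActiveImprover", 0) > 0:
            if self.archetypes["ActiveImprover"].trend_slope <= 0:
                raise ConfigError("ActiveImprover requires a positive trend_slope")
        if self.n_per_archetype.get("ActiveDecliner", 0) > 0:
            if self.archetypes["ActiveDecliner"].trend_slope >= 0:
                raise ConfigError("ActiveDecliner requires a negative trend_slope")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_per_archetype": dict(self.n_per_archetype),
            "archetypes": {
                arc: {
                    "picture_count": p.picture_count.to_dict(),
                    "usage_period": p.usage_period.to_dict(),
                    "trend_slope": p.trend_slope,
                    "p_description": p.p_description,
                    "description_length": p.description_length.to_dict(),
                    "p_like": p.p_like,
                    "p_comment": p.p_comment,
                }
                for arc, p in self.archetypes.items()
            },
            "rating_count": self.rating_count.to_dict(),
            "baseline_rating": self.baseline_rating.to_dict(),
            "rating_noise_sd": self.rating_noise_sd,
            "self_rating_noise_sd": self.self_rating_noise_sd,
            "p_self_rating": self.p_self_rating,
            "p_empty_picture": self.p_empty_picture,
            "p_test_first_picture": self.p_test_first_picture,
            "p_missing_registration": self.p_missing_registration,
            "p_second_diet_response": self.p_second_diet_response,
            "registration_grid": np.asarray(self.registration_grid, float).tolist(),
            "diet_weights": dict(self.diet_weights),
            "tz_weights": {int(k): float(v) for k, v in self.tz_weights.items()},
            "start_sunday": self.start_sunday,
            "n_weeks": self.n_weeks,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        base = cls()
        archetypes = dict(base.archetypes)
        for arc, p in d.get("archetypes", {}).items():
            defaults = archetypes.get(arc, ArchetypeParams(Law("constant", 0), Law("constant", 0)))
            archetypes[arc] = ArchetypeParams(
                picture_count=Law.from_dict(p["picture_count"])
                if "picture_count" in p else defaults.picture_count,
                usage_period=Law.from_dict(p["usage_period"])
                if "usage_period" in p else defaults.usage_period,
                trend_slope=p.get("trend_slope", defaults.trend_slope),
                p_description=p.get("p_description", defaults.p_description),
                description_length=Law.from_dict(p["description_length"])
                if "description_length" in p else defaults.description_length,
                p_like=p.get("p_like", defaults.p_like),
                p_comment=p.get("p_comment", defaults.p_comment),
            )
        kwargs: dict = {"archetypes": archetypes}
        for key in (
            "n_per_archetype", "rating_noise_sd", "self_rating_noise_sd",
            "p_self_rating", "p_empty_picture", "p_test_first_picture",
            "p_missing_registration", "p_second_diet_response", "diet_weights",
            "start_sunday", "n_weeks", "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "tz_weights" in d:
            kwargs["tz_weights"] = {int(k): float(v) for k, v in d["tz_weights"].items()}
        if "rating_count" in d:
            kwargs["rating_count"] = Law.from_dict(d["rating_count"])
        if "baseline_rating" in d:
            kwargs["baseline_rating"] = Law.from_dict(d["baseline_rating"])
        if "registration_grid" in d:
            kwargs["registration_grid"] = np.asarray(d["registration_grid"], dtype=float)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def expected_class_counts(config: CohortConfig) -> dict[Adherence, int]:
    """Adherence class counts the pipeline must recover on a generated cohort
    (exact whenever drawn counts respect archetype bounds and the validity
    rule is not triggered)."""
    counts = {cls: 0 for cls in Adherence}
    for arc, n in config.n_per_archetype.items():
        counts[ARCHETYPE_ADHERENCE[arc]] += int(n)
    return counts


def _random_text(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Deterministic filler text: lowercase letters and spaces."""
    total = int(lengths.sum())
    if total == 0:
        return ["" for _ in lengths]
    alphabet = np.frombuffer(b"abcdefghijklmnopqrstuvwxyz etaoinshr", dtype="S1")
    chars = alphabet[rng.integers(0, len(alphabet), total)]
    blob = b"".join(chars.tolist()).decode()
    ends = np.cumsum(lengths)
    starts = ends - lengths
    return [blob[s:e].strip() or "x" for s, e in zip(starts, ends)]


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Generate a full five-table cohort from ``config``.

    Fully reproducible: the same config and seed give byte-identical tables.
    The ground-truth archetype of each user is available (unserialized) as
    ``cohort.meta["archetype"]``, a Series indexed by user_id.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    arch_names = [a for a in ARCHETYPES if config.n_per_archetype.get(a, 0) > 0]
    arch_of_user = np.repeat(
        np.array(arch_names, dtype=object),
        [config.n_per_archetype[a] for a in arch_names],
    )
    n_users = len(arch_of_user)
    user_ids = np.array([f"u{i:07d}" for i in range(n_users)], dtype=object)

    # --- users table ------------------------------------------------------
    grid = np.asarray(config.registration_grid, dtype=float).ravel()
    cell = rng.choice(35, size=n_users, p=grid / grid.sum())
    weekday = cell // 5
    interval = cell % 5
    week = rng.integers(0, config.n_weeks, n_users)
    int_start = np.array([0, 5, 10, 15, 19], dtype=float)
    int_len = np.array([5, 5, 5, 4, 5], dtype=float)
    hours = int_start[interval] + rng.random(n_users) * int_len[interval]
    base = pd.Timestamp(config.start_sunday)
    registered = (
        base
        + pd.to_timedelta(week * 7 + weekday, unit="D")
        + pd.to_timedelta(np.floor(hours * 3600.0), unit="s")
    )
    registered = pd.Series(registered).dt.floor("s")
    missing = rng.random(n_users) < config.p_missing_registration
    registered = registered.mask(missing, pd.NaT)

    tz_keys = np.array(sorted(config.tz_weights))
    tz_w = np.array([config.tz_weights[k] for k in tz_keys], dtype=float)
    tz = pd.array(tz_keys[rng.choice(len(tz_keys), n_users, p=tz_w / tz_w.sum())], dtype="Int64")
    tz[missing] = pd.NA

    diet_keys = np.array(sorted(config.diet_weights), dtype=object)
    diet_w = np.array([config.diet_weights[k] for k in diet_keys], dtype=float)
    first_resp = diet_keys[rng.choice(len(diet_keys), n_users, p=diet_w / diet_w.sum())]
    second_mask = (rng.random(n_users) < config.p_second_diet_response) & (first_resp != "")
    nonempty = diet_keys[diet_keys != ""]
    second_resp = nonempty[rng.integers(0, len(nonempty), n_users)]
    diet_responses = np.where(
        second_mask & (second_resp != first_resp),
        first_resp + ";" + second_resp,
        first_resp,
    )

    users = pd.DataFrame(
        {
            "user_id": user_ids,
            "registered_at": registered,
            "tz_offset_hours": tz,
            "diet_responses": diet_responses.astype(object),
        }
    )

    # --- per-user usage draws --------------------------------------------
    n_pics = np.zeros(n_users, dtype=int)
    period = np.zeros(n_users)
    slope_u = np.zeros(n_users)
    p_desc_u = np.zeros(n_users)
    p_like_u = np.zeros(n_users)
    p_comment_u = np.zeros(n_users)
    for arc in arch_names:
        mask = arch_of_user == arc
        params = config.archetypes[arc]
        m = int(mask.sum())
        n_pics[mask] = np.maximum(0, np.rint(params.picture_count.sample(rng, m))).astype(int)
        period[mask] = np.maximum(0.0, params.usage_period.sample(rng, m))
        slope_u[mask] = params.trend_slope
        p_desc_u[mask] = params.p_description
        p_like_u[mask] = params.p_like
        p_comment_u[mask] = params.p_comment
    period[n_pics <= 1] = 0.0

    baseline = np.clip(config.baseline_rating.sample(rng, n_users), 0.02, 0.98)

    # anchor every user's pictures on a concrete local time, drawing a
    # registration-like stand-in when the stored timestamp is missing
    anchor = registered.copy()
    if missing.any():
        n_miss = int(missing.sum())
        fb_week = rng.integers(0, config.n_weeks, n_miss)
        fb_day = rng.integers(0, 7, n_miss)
        fb_hours = rng.random(n_miss) * 24.0
        anchor[missing] = (
            base
            + pd.to_timedelta(fb_week * 7 + fb_day, unit="D")
            + pd.to_timedelta(np.floor(fb_hours * 3600.0), unit="s")
        )

    # --- non-empty pictures ----------------------------------------------
    total_p = int(n_pics.sum())
    owner = np.repeat(np.arange(n_users), n_pics)
    ordinal = np.arange(total_p) - np.repeat(np.cumsum(n_pics) - n_pics, n_pics) + 1

    frac = rng.random(total_p)
    is_first = ordinal == 1
    is_last = ordinal == n_pics[owner]
    frac[is_first] = 0.0
    frac[is_last] = 1.0
    order = np.lexsort((frac, owner))
    frac = frac[order]  # ascending within each owner block

    # whole-second offsets keep the first-to-last elapsed time exactly equal
    # to the drawn usage period (never rounding an Active below the 7-day bound)
    start_offset_s = rng.integers(0, 7200, n_users)
    t0 = anchor.to_numpy() + start_offset_s.astype("timedelta64[s]")
    pic_offset_s = np.round(frac * period[owner] * 86400.0).astype(np.int64)
    taken = pd.Series(t0[owner] + pic_offset_s.astype("timedelta64[s]"))

    noise = rng.normal(0.0, config.rating_noise_sd, total_p)
    target = np.clip(baseline[owner] + slope_u[owner] * (ordinal - 1) + noise, 0.0, 1.0)

    self_mask = rng.random(total_p) < config.p_self_rating
    self_rating = np.where(
        self_mask,
        np.clip(target + rng.normal(0.0, config.self_rating_noise_sd, total_p), 0.0, 1.0),
        np.nan,
    )

    desc_mask = rng.random(total_p) < p_desc_u[owner]
    desc_len = np.zeros(total_p, dtype=int)
    for arc in arch_names:
        m = desc_mask & (arch_of_user[owner] == arc)
        if m.any():
            law = config.archetypes[arc].description_length
            desc_len[m] = np.maximum(1, np.rint(law.sample(rng, int(m.sum())))).astype(int)
    descriptions = np.array(_random_text(rng, desc_len), dtype=object)
    descriptions[~desc_mask] = ""

    n_ratings = np.maximum(0, np.rint(config.rating_count.sample(rng, total_p))).astype(int)
    test_first = is_first & (rng.random(total_p) < config.p_test_first_picture)
    n_ratings[test_first] = rng.integers(0, 10, int(test_first.sum()))

    # --- empty pictures ---------------------------------------------------
    n_empty = rng.binomial(np.maximum(n_pics, 1), config.p_empty_picture)
    total_e = int(n_empty.sum())
    e_owner = np.repeat(np.arange(n_users), n_empty)
    e_span = np.maximum(period[e_owner], 0.2) * 86400.0
    e_taken = pd.Series(
        t0[e_owner] + np.round(rng.random(total_e) * e_span).astype(np.int64).astype("timedelta64[s]")
    )

    # --- assemble pictures, assign ids chronologically per user -----------
    pics = pd.DataFrame(
        {
            "_owner": np.concatenate([owner, e_owner]),
            "taken_at": pd.concat([taken, e_taken], ignore_index=True),
            "has_image": np.concatenate(
                [np.ones(total_p, bool), np.zeros(total_e, bool)]
            ),
            "self_rating": np.concatenate([self_rating, np.full(total_e, np.nan)]),
            "description": np.concatenate([descriptions, np.full(total_e, "", object)]),
            "_target": np.concatenate([target, np.zeros(total_e)]),
            "_n_ratings": np.concatenate([n_ratings, np.zeros(total_e, int)]),
        }
    )
    pics = pics.sort_values(["_owner", "taken_at", "has_image"], kind="mergesort").reset_index(
        drop=True
    )
    pics["picture_id"] = [f"p{i:08d}" for i in range(len(pics))]
    pics["user_id"] = user_ids[pics["_owner"].to_numpy()]

    # --- peer ratings: n draws whose mean is shifted onto the target ------
    c = pics["_n_ratings"].to_numpy()
    rated = np.flatnonzero(c > 0)
    c_r = c[rated]
    total_r = int(c_r.sum())
    pic_rep = np.repeat(rated, c_r)
    r_starts = np.concatenate(([0], np.cumsum(c_r)))[:-1]
    eps = rng.uniform(-1.0, 1.0, total_r)
    group_mean = np.add.reduceat(eps, r_starts) / c_r
    centered = eps - np.repeat(group_mean, c_r)
    maxabs = np.maximum.reduceat(np.abs(centered), r_starts)
    m_target = pics["_target"].to_numpy()[rated]
    room = np.minimum(m_target, 1.0 - m_target)
    scale = np.where(maxabs > 0, np.minimum(1.0, room / np.where(maxabs > 0, maxabs, 1.0)), 0.0)
    values = np.clip(np.repeat(m_target, c_r) + centered * np.repeat(scale, c_r), 0.0, 1.0)

    rater = user_ids[rng.integers(0, n_users, total_r)]
    rated_at = (
        pics["taken_at"].to_numpy()[pic_rep]
        + (rng.random(total_r) * 3 * 86400.0).astype("timedelta64[s]")
    )
    ratings = pd.DataFrame(
        {
            "rating_id": [f"r{i:09d}" for i in range(total_r)],
            "picture_id": pics["picture_id"].to_numpy()[pic_rep],
            "rater_id": rater,
            "value": values,
            "rated_at": pd.Series(rated_at).dt.floor("s"),
        }
    )

    # --- likes and comments ----------------------------------------------
    has_img = pics["has_image"].to_numpy()
    p_like_pic = np.where(has_img, p_like_u[pics["_owner"].to_numpy()], 0.0)
    p_comm_pic = np.where(has_img, p_comment_u[pics["_owner"].to_numpy()], 0.0)
    liked = rng.random(len(pics)) < p_like_pic
    n_likes = np.where(liked, 1 + rng.poisson(0.3, len(pics)), 0)
    like_rep = np.repeat(np.arange(len(pics)), n_likes)
    likes = pd.DataFrame(
        {
            "picture_id": pics["picture_id"].to_numpy()[like_rep],
            "peer_id": user_ids[rng.integers(0, n_users, len(like_rep))],
        }
    )
    commented = rng.random(len(pics)) < p_comm_pic
    n_comm = np.where(commented, 1 + rng.poisson(0.4, len(pics)), 0)
    comm_rep = np.repeat(np.arange(len(pics)), n_comm)
    comm_len = rng.integers(5, 60, len(comm_rep))
    comments = pd.DataFrame(
        {
            "picture_id": pics["picture_id"].to_numpy()[comm_rep],
            "peer_id": user_ids[rng.integers(0, n_users, len(comm_rep))],
            "text": _random_text(rng, comm_len),
        }
    )

    pictures = pics[
        ["picture_id", "user_id", "taken_at", "has_image", "self_rating", "description"]
    ].copy()
    cohort = Cohort(
        users,
        pictures,
        ratings,
        likes,
        comments,
        meta={"archetype": pd.Series(arch_of_user, index=user_ids)},
    )
    logger.info(
        "generated cohort: %d users, %d pictures (%d empty), %d ratings, %d likes, %d comments",
        n_users, len(pictures), total_e, total_r, len(likes), len(comments),
    )
    return cohort
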