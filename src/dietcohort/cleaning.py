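"""Exclusion pipeline: empty-picture removal, first-picture validity, summaries.

The raw log contains "empty" entries with no actual image, and for some users
the first picture was a test shot of something other than food. Test shots
are identified by a low crowd-rating count: a picture is *valid* when it has
received at least ``threshold`` (default 10) peer ratings. Only a user's
first two pictures are ever checked; later pictures count unconditionally.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_VALIDITY_THRESHOLD = 10

__all__ = [
    "drop_empty_pictures",
    "summarize_pictures",
    "apply_validity_rule",
    "apply_validity_cohort",
    "DEFAULT_VALIDITY_THRESHOLD",
]


def drop_empty_pictures(pictures: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove entries that contain no actual image.

    Returns the ``has_image`` rows and the number of rows removed.
    """
    kept = pictures[pictures["has_image"]].copy()
    n_removed = len(pictures) - len(kept)
    logger.info("removed %d empty pictures, %d remain", n_removed, len(kept))
    return kept, n_removed


def summarize_pictures(
    pictures: pd.DataFrame,
    ratings: pd.DataFrame,
    likes: pd.DataFrame,
    comments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-picture derived metrics for cleaned (non-empty) pictures.

    One row per picture: chronological ``ordinal`` within its owner (ties
    broken by ascending picture_id), mean peer rating, rating/like/comment
    counts, description length in characters (0 = no description), and the
    self-minus-peer rating difference where both sides exist.
    """
    out = pictures.sort_values(
        ["user_id", "taken_at", "picture_id"], kind="mergesort"
    ).reset_index(drop=True)

    grp = ratings.groupby("picture_id")["value"]
    n_ratings = grp.size()
    avg = grp.mean()
    n_likes = likes.groupby("picture_id").size()
    n_comments = comments.groupby("picture_id").size()

    pid = out["picture_id"]
    out["ordinal"] = out.groupby("user_id").cumcount() + 1
    out["n_ratings"] = pid.map(n_ratings).fillna(0).astype(int)
    out["avg_peer_rating"] = pid.map(avg)
    out["n_likes"] = pid.map(n_likes).fillna(0).astype(int)
    out["n_comments"] = pid.map(n_comments).fillna(0).astype(int)
    out["description_length"] = out["description"].fillna("").str.len().astype(int)
    out["self_vs_peer_diff"] = out["self_rating"] - out["avg_peer_rating"]
    return out[
        [
            "picture_id",
            "user_id",
            "taken_at",
            "ordinal",
            "avg_peer_rating",
            "n_ratings",
            "n_likes",
            "n_comments",
            "description_length",
            "self_vs_peer_diff",
            "self_rating",
        ]
    ]


def apply_validity_rule(
    rating_counts: Sequence[int], threshold: int = DEFAULT_VALIDITY_THRESHOLD
) -> tuple[int | None, int]:
    """First-picture validity rule for one user's ordered pictures.

    ``rating_counts`` are peer-rating counts in chronological order. If the
    first picture has at least ``threshold`` ratings it is the first valid
    picture and nothing is excluded. Otherwise the second picture (if any)
    is checked and, when valid, used instead, excluding the first. If
    neither of the first two qualifies, the user has no valid first picture
    and both checked pictures are excluded. Pictures beyond the second are
    never examined, so the count drops by at most two.

    Returns ``(index_of_first_valid or None, adjusted_count)`` with a
    0-based index into ``rating_counts``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    n = len(rating_counts)
    if n == 0:
        return None, 0
    if rating_counts[0] >= threshold:
        return 0, n
    if n >= 2 and rating_counts[1] >= threshold:
        return 1, n - 1
    return None, n - min(n, 2)


def apply_validity_cohort(
    summaries: pd.DataFrame, threshold: int = DEFAULT_VALIDITY_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series]:
    """Vectorized validity rule over a whole cohort's picture summaries.

    ``summaries`` is the output of :func:`summarize_pictures`. Returns

    - a per-user frame (``user_id``, ``first_valid_picture_id`` or NA,
      ``n_valid_pictures``), and
    - a boolean ``counted`` mask aligned with ``summaries`` marking pictures
      that survive the adjustment (excluded first/second pictures are False).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    s = summaries
    first_two = s[s["ordinal"] <= 2]
    wide = first_two.pivot(index="user_id", columns="ordinal", values="n_ratings")
    wide = wide.reindex(columns=[1, 2])
    r1 = wide[1].to_numpy(dtype=float)
    r2 = wide[2].to_numpy(dtype=float)  # NaN when no second picture
    pid_wide = first_two.pivot(index="user_id", columns="ordinal", values="picture_id")
    pid_wide = pid_wide.reindex(columns=[1, 2])

    total = s.groupby("user_id").size().reindex(wide.index).to_numpy()

    valid1 = r1 >= threshold
    valid2 = ~np.isnan(r2) & (r2 >= threshold)
    first_valid = np.where(
        valid1, pid_wide[1], np.where(valid2, pid_wide[2], None)
    )
    n_excluded = np.where(valid1, 0, np.where(valid2, 1, np.minimum(total, 2)))
    per_user = pd.DataFrame(
        {
            "user_id": wide.index,
            "first_valid_picture_id": first_valid,
            "n_valid_pictures": (total - n_excluded).astype(int),
        }
    ).reset_index(drop=True)

    drop1 = pd.Series(~valid1, index=wide.index)
    drop2 = pd.Series(~valid1 & ~valid2, index=wide.index)
    uid = s["user_id"]
    counted = ~(
        ((s["ordinal"] == 1) & uid.map(drop1).fillna(False).astype(bool))
        | ((s["ordinal"] == 2) & uid.map(drop2).fillna(False).astype(bool))
    )
    counted.name = "counted"

    n_dropped = int((~counted).sum())
    logger.info(
        "validity rule (threshold %d): excluded %d of %d pictures; %d users with no valid first picture",
        threshold,
        n_dropped,
        len(s),
        int(per_user["first_valid_picture_id"].isna().sum()),
    )
    return per_user, counted
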