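"""End-to-end pipeline: cleaning, classification, inference, trend analysis.

:func:`run_pipeline` turns a raw five-table cohort into a report bundle of
machine-readable tables mirroring the standard presentation of this kind of
adherence study: an adherence breakdown, valid-picture statistics,
diet x adherence proportions with chi-square and Tukey comparisons,
first-picture engagement and peer-feedback comparisons, a trend analysis by
diet category, and a 7 x 5 registration-grid enrichment scan. Every
exclusion (empty pictures, invalid first pictures, missing registration
times, missing self-ratings) is counted in an exclusion ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, classify, inference, trends
from .model import Adherence, Cohort, DayInterval, DietCategory, DAY_INTERVALS, TestResult, TrendClass
from .model import split_diet_responses

logger = logging.getLogger(__name__)

__all__ = ["PipelineSettings", "ReportBundle", "summarize_users", "run_pipeline", "write_report"]

ADHERENCE_ORDER = [
    Adherence.NON_USER,
    Adherence.NON_ACTIVE,
    Adherence.SEMI_ACTIVE,
    Adherence.ACTIVE,
]
DIET_ORDER = [
    DietCategory.NOT_DEFINED,
    DietCategory.EVERYTHING,
    DietCategory.STRICT,
    DietCategory.OTHER,
]
FEEDBACK_GROUPS = [Adherence.NON_ACTIVE, Adherence.SEMI_ACTIVE, Adherence.ACTIVE]


@dataclass(frozen=True)
class PipelineSettings:
    """Tunable analysis parameters (defaults match the published protocol)."""

    validity_threshold: int = cleaning.DEFAULT_VALIDITY_THRESHOLD
    alpha: float = 0.05
    grid_alpha: float = 0.05
    min_pictures: int = classify.ACTIVE_MIN_PICTURES
    min_period_days: float = classify.ACTIVE_MIN_PERIOD_DAYS
    study_end: str | None = None  # flag (never reclassify) late registrants


@dataclass
class ReportBundle:
    """All pipeline outputs: per-user/picture frames, report tables, tests."""

    user_summaries: pd.DataFrame
    picture_summaries: pd.DataFrame
    trend_table: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: dict[str, TestResult] = field(default_factory=dict)
    tukey: dict[str, inference.TukeyResult] = field(default_factory=dict)
    grid: inference.GridScanResult | None = None
    exclusions: dict[str, int] = field(default_factory=dict)


def summarize_users(cohort: Cohort, settings: PipelineSettings = PipelineSettings()) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Cleaning + per-user classification for a whole cohort.

    Returns (user_summaries, picture_summaries-with-counted-mask,
    exclusion counts). Every user of the cohort appears exactly once in the
    summaries, including users with no pictures at all.
    """
    exclusions: dict[str, int] = {}
    nonempty, n_empty = cleaning.drop_empty_pictures(cohort.pictures)
    exclusions["empty_pictures"] = n_empty

    summaries = cleaning.summarize_pictures(nonempty, cohort.ratings, cohort.likes, cohort.comments)
    per_user, counted = cleaning.apply_validity_cohort(summaries, settings.validity_threshold)
    summaries = summaries.assign(counted=counted.to_numpy())
    exclusions["invalid_first_pictures"] = int((~counted).sum())

    kept = summaries[summaries["counted"]]
    span = kept.groupby("user_id")["taken_at"].agg(["min", "max", "size"])
    period = (span["max"] - span["min"]).dt.total_seconds() / 86400.0
    period = period.where(span["size"] > 1, 0.0)

    users = cohort.users.set_index("user_id")
    out = pd.DataFrame(index=users.index)
    out["n_valid_pictures"] = per_user.set_index("user_id")["n_valid_pictures"].reindex(out.index).fillna(0).astype(int)
    out["usage_period_days"] = period.reindex(out.index).fillna(0.0)
    out["pictures_per_day"] = out["n_valid_pictures"] / np.maximum(out["usage_period_days"], 1.0)
    out["n_ratings_given"] = (
        cohort.ratings.groupby("rater_id").size().reindex(out.index).fillna(0).astype(int)
    )
    out["adherence"] = classify.classify_adherence_arrays(
        out["n_valid_pictures"].to_numpy(),
        out["usage_period_days"].to_numpy(),
        settings.min_pictures,
        settings.min_period_days,
    )
    out["diet_category"] = users["diet_responses"].map(
        lambda s: classify.categorize_diet(split_diet_responses(s))
    )
    bins = classify.bin_registration_series(users["registered_at"])
    out["reg_weekday"] = bins["reg_weekday"].to_numpy()
    out["reg_interval"] = bins["reg_interval"].to_numpy()
    out["first_valid_picture_id"] = (
        per_user.set_index("user_id")["first_valid_picture_id"].reindex(out.index)
    )
    if settings.study_end is not None:
        end = pd.Timestamp(settings.study_end)
        out["late_registration"] = users["registered_at"] > end - pd.Timedelta(days=7)

    exclusions["users_without_registration_time"] = int(users["registered_at"].isna().sum())
    first_valid = summaries.merge(
        out["first_valid_picture_id"].dropna().rename("pid"),
        left_on="picture_id", right_on="pid", how="inner",
    )
    exclusions["users_without_first_self_rating"] = int(first_valid["self_rating"].isna().sum())
    return out.reset_index(), summaries, exclusions


def _proportion_block(
    name: str,
    labels: list[str],
    successes: list[int],
    totals: list[int],
    alpha: float,
    bundle: ReportBundle,
) -> dict:
    """Run chi-square + Tukey on one proportion row; degenerate rows are skipped."""
    keep = [i for i, t in enumerate(totals) if t > 0]
    if len(keep) < 2:
        logger.warning("%s: fewer than 2 non-empty groups, test skipped", name)
        return {}
    table = inference.ProportionTable(
        tuple(labels[i] for i in keep),
        tuple(successes[i] for i in keep),
        tuple(totals[i] for i in keep),
    )
    if sum(table.successes) in (0, sum(table.totals)):
        logger.warning("%s: all successes or all failures, test skipped", name)
        return {}
    res = inference.chi2_homogeneity(table)
    tk = inference.tukey_hsd_proportions(table, alpha)
    bundle.tests[name] = res
    bundle.tukey[name] = tk
    return {
        "statistic": res.statistic,
        "df": res.df[0],
        "p_value": res.p_value,
        "significant_pairs": _pairs_str(tk),
    }


def _anova_block(
    name: str,
    groups: dict[str, np.ndarray],
    alpha: float,
    bundle: ReportBundle,
) -> dict:
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2 or sum(len(v) for v in usable.values()) <= len(usable):
        logger.warning("%s: not enough groups/observations, ANOVA skipped", name)
        return {}
    res = inference.anova_oneway(list(usable.values()))
    tk = inference.tukey_hsd_means(list(usable.values()), list(usable.keys()), alpha)
    bundle.tests[name] = res
    bundle.tukey[name] = tk
    return {
        "statistic": res.statistic,
        "df": f"({res.df[0]:.0f}, {res.df[1]:.0f})",
        "p_value": res.p_value,
        "significant_pairs": _pairs_str(tk),
    }


def _pairs_str(tk: inference.TukeyResult) -> str:
    return ";".join(f"{a}|{b}" for a, b in sorted(tk.significant))


def run_pipeline(cohort: Cohort, settings: PipelineSettings = PipelineSettings()) -> ReportBundle:
    """Run the full analysis and assemble the report bundle."""
    users, pictures, exclusions = summarize_users(cohort, settings)
    trend_table, trend_counts = trends.classify_cohort_trends(users, pictures, settings.alpha)
    bundle = ReportBundle(users, pictures, trend_table, exclusions=exclusions)

    alpha = settings.alpha
    adh = users["adherence"]

    # --- adherence breakdown (counts + usage moments) ---------------------
    rows = []
    for cls in ADHERENCE_ORDER:
        sub = users[adh == cls]
        row = {
            "group": "Dropouts" if cls in (Adherence.NON_USER, Adherence.NON_ACTIVE) else "Users",
            "activity_level": cls.value,
            "count": len(sub),
            "pct": 100.0 * len(sub) / max(len(users), 1),
        }
        if cls in (Adherence.SEMI_ACTIVE, Adherence.ACTIVE) and len(sub) >= 2:
            row["pictures_mean"] = sub["n_valid_pictures"].mean()
            row["pictures_sd"] = sub["n_valid_pictures"].std(ddof=1)
            row["period_mean"] = sub["usage_period_days"].mean()
            row["period_sd"] = sub["usage_period_days"].std(ddof=1)
        rows.append(row)
    bundle.tables["adherence"] = pd.DataFrame(rows)

    # --- valid picture statistics ----------------------------------------
    valid = pictures[pictures["counted"]]
    desc = valid[valid["description_length"] > 0]
    liked = valid[valid["n_likes"] > 0]
    commented = valid[valid["n_comments"] > 0]
    rated = valid[valid["avg_peer_rating"].notna()]
    bundle.tables["pictures"] = pd.DataFrame(
        [
            {
                "n_valid_pictures": len(valid),
                "n_with_description": len(desc),
                "pct_with_description": 100.0 * len(desc) / max(len(valid), 1),
                "description_length_mean": desc["description_length"].mean(),
                "description_length_sd": desc["description_length"].std(ddof=1),
                "avg_rating_mean": rated["avg_peer_rating"].mean(),
                "avg_rating_sd": rated["avg_peer_rating"].std(ddof=1),
                "n_with_like": len(liked),
                "pct_with_like": 100.0 * len(liked) / max(len(valid), 1),
                "likes_mean_if_any": liked["n_likes"].mean(),
                "n_with_comment": len(commented),
                "pct_with_comment": 100.0 * len(commented) / max(len(valid), 1),
                "comments_mean_if_any": commented["n_comments"].mean(),
            }
        ]
    )

    # --- diet x adherence proportions ------------------------------------
    with_valid = users[users["n_valid_pictures"] >= 1]
    diet_labels = [d.value for d in DIET_ORDER]
    totals = [int((with_valid["diet_category"] == d).sum()) for d in DIET_ORDER]
    actives = [
        int(((with_valid["diet_category"] == d) & (adh.loc[with_valid.index] == Adherence.ACTIVE)).sum())
        for d in DIET_ORDER
    ]
    users_n = [
        int(((with_valid["diet_category"] == d) & (with_valid["n_valid_pictures"] >= 2)).sum())
        for d in DIET_ORDER
    ]
    diet_rows = []
    for row_name, succ in (("actives_of_with_valid", actives), ("users_of_with_valid", users_n)):
        row = {"row": row_name}
        for lbl, s, t in zip(diet_labels, succ, totals):
            row[f"{lbl}_n"] = s
            row[f"{lbl}_total"] = t
            row[f"{lbl}_pct"] = 100.0 * s / t if t else np.nan
        row.update(_proportion_block(f"diet_{row_name}", diet_labels, succ, totals, alpha, bundle))
        diet_rows.append(row)
    bundle.tables["diet_adherence"] = pd.DataFrame(diet_rows)

    # --- first-picture engagement and peer feedback ----------------------
    eligible = users[users["first_valid_picture_id"].notna()]
    fp = pictures.merge(
        eligible[["user_id", "first_valid_picture_id", "adherence"]].rename(
            columns={"first_valid_picture_id": "picture_id", "adherence": "adh"}
        ),
        on=["user_id", "picture_id"],
        how="inner",
    )
    group_labels = [c.value for c in FEEDBACK_GROUPS]
    by_group = {c: fp[fp["adh"] == c] for c in FEEDBACK_GROUPS}
    g_tot = [len(by_group[c]) for c in FEEDBACK_GROUPS]

    desc_rows = []
    row = {"row": "has_description"}
    succ = [int((by_group[c]["description_length"] > 0).sum()) for c in FEEDBACK_GROUPS]
    for lbl, s, t in zip(group_labels, succ, g_tot):
        row[f"{lbl}_n"] = s
        row[f"{lbl}_pct"] = 100.0 * s / t if t else np.nan
    row.update(_proportion_block("first_picture_description", group_labels, succ, g_tot, alpha, bundle))
    desc_rows.append(row)
    row = {"row": "description_length_if_any"}
    groups = {
        c.value: by_group[c].loc[by_group[c]["description_length"] > 0, "description_length"].to_numpy(float)
        for c in FEEDBACK_GROUPS
    }
    for lbl in group_labels:
        g = groups[lbl]
        row[f"{lbl}_mean"] = g.mean() if len(g) else np.nan
        row[f"{lbl}_sd"] = g.std(ddof=1) if len(g) > 1 else np.nan
    row.update(_anova_block("first_picture_description_length", groups, alpha, bundle))
    desc_rows.append(row)
    bundle.tables["first_picture_description"] = pd.DataFrame(desc_rows)

    fb_rows = []
    for row_name, col in (
        ("avg_peer_rating", "avg_peer_rating"),
        ("self_vs_peer_diff", "self_vs_peer_diff"),
    ):
        row = {"row": row_name}
        groups = {
            c.value: by_group[c][col].dropna().to_numpy(float) for c in FEEDBACK_GROUPS
        }
        for lbl in group_labels:
            g = groups[lbl]
            row[f"{lbl}_mean"] = g.mean() if len(g) else np.nan
            row[f"{lbl}_sd"] = g.std(ddof=1) if len(g) > 1 else np.nan
        row.update(_anova_block(f"first_picture_{row_name}", groups, alpha, bundle))
        fb_rows.append(row)
    for row_name, col in (("has_like", "n_likes"), ("has_comment", "n_comments")):
        row = {"row": row_name}
        succ = [int((by_group[c][col] > 0).sum()) for c in FEEDBACK_GROUPS]
        for lbl, s, t in zip(group_labels, succ, g_tot):
            row[f"{lbl}_n"] = s
            row[f"{lbl}_pct"] = 100.0 * s / t if t else np.nan
        row.update(_proportion_block(f"first_picture_{row_name}", group_labels, succ, g_tot, alpha, bundle))
        fb_rows.append(row)
        row = {"row": f"{col}_if_any"}
        groups = {
            c.value: by_group[c].loc[by_group[c][col] > 0, col].to_numpy(float)
            for c in FEEDBACK_GROUPS
        }
        for lbl in group_labels:
            g = groups[lbl]
            row[f"{lbl}_mean"] = g.mean() if len(g) else np.nan
            row[f"{lbl}_sd"] = g.std(ddof=1) if len(g) > 1 else np.nan
        row.update(_anova_block(f"first_picture_{col}_if_any", groups, alpha, bundle))
        fb_rows.append(row)
    bundle.tables["first_picture_feedback"] = pd.DataFrame(fb_rows)

    # --- trend analysis among eligible Actives, by diet -------------------
    tt = trend_table.merge(users, on="user_id", how="left")
    fp_rating = fp.set_index("user_id")["avg_peer_rating"]
    all_mean = (
        pictures[pictures["counted"] & pictures["avg_peer_rating"].notna()]
        .groupby("user_id")["avg_peer_rating"]
        .mean()
    )
    trend_rows = []
    diet_groups = {d: tt[tt["diet_category"] == d] for d in DIET_ORDER}
    t_tot = [len(diet_groups[d]) for d in DIET_ORDER]
    for row_name, source in (("first_picture_rating", fp_rating), ("all_pictures_rating", all_mean)):
        row = {"row": row_name}
        groups = {
            d.value: source.reindex(diet_groups[d]["user_id"]).dropna().to_numpy(float)
            for d in DIET_ORDER
        }
        for lbl in diet_labels:
            g = groups[lbl]
            row[f"{lbl}_mean"] = g.mean() if len(g) else np.nan
            row[f"{lbl}_sd"] = g.std(ddof=1) if len(g) > 1 else np.nan
        row.update(_anova_block(f"trend_{row_name}", groups, alpha, bundle))
        trend_rows.append(row)
    for cls, row_name in ((TrendClass.IMPROVER, "improvers"), (TrendClass.DECLINER, "decliners")):
        row = {"row": row_name}
        succ = [int((diet_groups[d]["classification"] == cls).sum()) for d in DIET_ORDER]
        for lbl, s, t in zip(diet_labels, succ, t_tot):
            row[f"{lbl}_n"] = s
            row[f"{lbl}_total"] = t
            row[f"{lbl}_pct"] = 100.0 * s / t if t else np.nan
        row.update(_proportion_block(f"trend_{row_name}", diet_labels, succ, t_tot, alpha, bundle))
        trend_rows.append(row)
    bundle.tables["trend_by_diet"] = pd.DataFrame(trend_rows)
    bundle.tables["trend_counts"] = pd.DataFrame(
        [{"classification": k, "count": v} for k, v in trend_counts.items()]
    )

    n_imp = trend_counts.get(TrendClass.IMPROVER.value, 0)
    n_other = len(trend_table) - n_imp
    if n_imp >= 2 and n_other >= 2:
        cmp = trends.compare_improvers(trend_table, users)
        bundle.tables["improver_comparison"] = pd.DataFrame(
            [
                {
                    "variable": var,
                    "t": r.statistic,
                    "df": r.df[0],
                    "p_value": r.p_value,
                }
                for var, r in cmp.items()
            ]
        )
        for var, r in cmp.items():
            bundle.tests[f"improvers_{var}"] = r
    else:
        logger.warning("improver comparison skipped: %d Improvers, %d others", n_imp, n_other)

    # --- registration grid scan ------------------------------------------
    binnable = users[users["reg_weekday"].notna()]
    if len(binnable):
        interval_idx = {iv: j for j, iv in enumerate(DAY_INTERVALS)}
        users_grid = np.zeros((7, 5))
        drop_grid = np.zeros((7, 5))
        is_user = (binnable["n_valid_pictures"] >= 2).to_numpy()
        wk = binnable["reg_weekday"].to_numpy(dtype=int)
        iv = binnable["reg_interval"].map(interval_idx).to_numpy(dtype=int)
        np.add.at(users_grid, (wk[is_user], iv[is_user]), 1)
        np.add.at(drop_grid, (wk[~is_user], iv[~is_user]), 1)
        if users_grid.sum() > 0 and drop_grid.sum() > 0:
            scan = inference.grid_proportion_scan(users_grid, drop_grid, settings.grid_alpha)
            bundle.grid = scan
            grid_rows = []
            for w in range(7):
                for j, iv_name in enumerate(DAY_INTERVALS):
                    grid_rows.append(
                        {
                            "weekday": w,
                            "interval": iv_name.value,
                            "users_n": int(users_grid[w, j]),
                            "dropouts_n": int(drop_grid[w, j]),
                            "label": scan.labels[w, j],
                            "chi2": scan.statistic[w, j],
                            "p_value": scan.p_value[w, j],
                        }
                    )
            bundle.tables["registration_grid"] = pd.DataFrame(grid_rows)
        else:
            logger.warning("registration grid scan skipped: one group is empty")
    else:
        logger.warning("registration grid scan skipped: no binnable users")

    bundle.tables["exclusions"] = pd.DataFrame(
        [{"exclusion": k, "count": v} for k, v in exclusions.items()]
    )
    return bundle


def plot_grid(bundle: ReportBundle, path: str | Path | None = None):
    """Render the registration-grid scan (requires matplotlib).

    Dark cells: higher proportion of Users started there; light cells:
    higher proportion of Dropouts; grey: no difference at the
    Bonferroni-corrected level.
    """
    if bundle.grid is None:
        raise ValueError("no grid scan in this bundle")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shade = {"users_enriched": 0.0, "no_difference": 0.55, "dropouts_enriched": 1.0}
    img = np.vectorize(shade.get)(bundle.grid.labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(img, cmap="gray", vmin=0, vmax=1)
    ax.set_xticks(range(5), [iv.value for iv in DAY_INTERVALS], rotation=30, ha="right")
    ax.set_yticks(range(7), ["Sun", "Mon", "Tue", "Wed", "Thu", "Fri", "Sat"])
    ax.set_title(
        f"Registration-time enrichment (black = Users, P < {bundle.grid.alpha_adjusted:.4f})"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def write_report(bundle: ReportBundle, directory: str | Path) -> list[Path]:
    """Write every report table as CSV plus a human-readable summary.txt."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables.items():
        path = directory / f"{name}.csv"
        table.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
        written.append(path)
    trend_path = directory / "trend_users.csv"
    tt = bundle.trend_table.copy()
    tt["classification"] = tt["classification"].map(lambda c: c.value)
    tt.to_csv(trend_path, index=False, lineterminator="\n", float_format="%.6g")
    written.append(trend_path)

    lines = ["Cohort analysis summary", "======================", ""]
    adh = bundle.tables["adherence"]
    for _, r in adh.iterrows():
        lines.append(f"{r['activity_level']:>12}: {int(r['count'])} users ({r['pct']:.2f}%)")
    lines.append("")
    lines.append("Exclusions:")
    for k, v in bundle.exclusions.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("Tests:")
    for name, res in bundle.tests.items():
        df = ",".join(f"{d:g}" for d in res.df)
        lines.append(f"  {name}: {res.kind}({df}) = {res.statistic:.4g}, p = {res.p_value:.4g}")
    summary = directory / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    logger.info("wrote report to %s (%d files)", directory, len(written))
    return written
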