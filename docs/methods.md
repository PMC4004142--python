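# Methods

## The data model

A cohort is five event-log tables. Timestamps are the *local civil time*
of the user's phone; the stored UTC offset is kept as metadata but never
applied, because the analyses (daypart binning in particular) are about the
user's own clock. Healthiness ratings live on a continuous 0–1 scale,
0 = "fat" (unhealthy), 1 = "fit" (healthy); a picture's healthiness is the
arithmetic mean of its peer ratings. Within a user, pictures are ordered
chronologically with ties broken by ascending picture id, which makes
ordinals (and therefore everything downstream) deterministic.

## Exclusion pipeline

1. **Empty pictures** (no actual image) are removed first.
2. **First-picture validity.** Test shots — a chair photographed to try the
   app out — are identified by a low crowd-rating count. A picture is valid
   when it has at least `threshold` (default 10, boundary inclusive) peer
   ratings. Only the first two pictures are ever checked: if the first is
   valid nothing happens; if only the second is, the first is excluded and
   the second becomes the user's first valid picture; if neither is, both
   are excluded and the user has no valid first picture (dropping the
   per-user count by at most two). Pictures from the third onward always
   count.
3. The **usage period** is the elapsed time, in fractional days, between a
   user's first and last *counted* picture (0 when fewer than two remain).
   Pictures per day divides by `max(period, 1)` so that single-day users
   are not divided by a near-zero interval.

## Classification

- **Adherence**: Non-user (0 valid pictures), Non-active (1), Active
  (≥ 10 pictures and period ≥ 7.0 days), Semi-active (the rest, ≥ 2
  pictures). The one-week bound is implemented inclusively (≥ 7.0 days)
  and is configurable; sources describing this design vary between "at
  least one week" and "longer than 7 days", and the inclusive reading
  keeps the boundary consistent with the inclusive 10-picture bound.
- **Diet**: matching is case-insensitive on the canonical onboarding answer
  strings. Precedence is Strict > Other > Everything > NotDefined: "Strict"
  is defined by *any* restrictive answer being present, "Other" is any
  non-"I eat everything!" answer, so a user answering both "I eat
  everything!" and "Low fat" is Strict. The categorization is invariant to
  answer order and duplication.
- **Registration bins**: weekday 0 = Sunday … 6 = Saturday, with five
  dayparts by hour, half-open on the right: night [0,5), morning [5,10),
  daytime [10,15), late afternoon [15,19), evening [19,24). Users without
  a registration time are unbinnable and excluded from (only) the
  registration analyses; a `study_end` setting flags, but never
  reclassifies, users who registered within a week of the sampling end.

## Inference

All chi-square statistics are plain Pearson sums Σ(O−E)²/E with **no
continuity correction** — this is what reproduces published
contingency-table statistics in this literature; Yates-corrected versions
do not. p-values are two-sided; summary-based forms (ANOVA from
means/SDs/ns, pooled *t*) assume the sample (n−1) SD convention.

The grid scan tests each of the 35 registration cells with a 2 × 2
chi-square of (cell vs rest) × (Users vs Dropouts) at the Bonferroni level
α/35; a significant cell is labelled by which group has the larger share
of its members registering there. Bonferroni keeps the family-wise error
at ≈ α across the 35 correlated tests (measured ≈ 4–5% at α = .05 on
homogeneous grids).

Tukey-type multiple comparison **of proportions** follows Zar's arcsine
procedure: φ = arcsin √p̂ has large-sample variance 1/(4n) independent of
p, so pairs are compared with the studentized range at infinite df using
the Tukey–Kramer standard error √(1/(8nᵢ) + 1/(8nⱼ)); proportions of
exactly 0 or 1 use the endpoint adjustment arcsin √(1/4n). The named
procedure for this analysis is underspecified in the applied literature;
this variant was chosen because it reproduces the published post-hoc
patterns of the reference cohort (all six diet pairs significant for the
Actives row; all but Strict–Other for the Users row) from the printed
counts alone. Tukey HSD on means uses MS_within from the one-way ANOVA
with the studentized range at df = n−k.

Degenerate inputs: a zero within-group variance with separated means
yields an infinite F (p = 0); identical constant groups yield F = 0
(p = 1); a 2 × 2 table with a zero margin is an error; a report-stage test
whose groups collapse (fewer than two non-empty groups, or all successes /
all failures) is skipped with a logged warning rather than failing the
run.

## Trend detection

For each Active user with a valid first-or-second picture, the mean peer
rating is regressed on the picture index 1…N (ordered list, not real
time). The slope is the closed form Sxy/Sxx with the usual t-test on N−2
df; classification is Improver/Decliner on a significant positive/negative
slope at α = .05. Pictures with no peer ratings at all are skipped, the
remaining pictures keeping their relative order; users with fewer than
three rated pictures cannot support the t-test and are recorded as NoTrend
so that Improver/Decliner/NoTrend always partitions the eligible Actives.
A perfectly linear nonconstant series has zero residual variance and is
treated as p = 0 with the slope's sign. Improvers are compared to all
other eligible Actives with pooled *t* tests on picture count, usage
period, and pictures per day.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular population's outcome rates. Users are drawn from archetypes
(NonUser, NonActive, SemiActive, Active, ActiveImprover, ActiveDecliner),
each with a picture-count law, usage-period law, trend slope, and
engagement rates. Default moments follow the published summaries of a
large commercial food-photography cohort: Semi-active counts uniform on
2–9 (mean ≈ 4) with exponential periods (mean 9.3 d); Active counts a
shifted negative binomial with mean ≈ 59 and SD ≈ 100, periods 7 d +
exponential (mean ≈ 47 d); ≈ 19 crowd ratings per picture (Poisson); 3%
empty pictures; 4% test first pictures (rating count uniform on 0–9);
1.49% missing registration times; diet answers at the published Table-2
shares; per-archetype description/like/comment rates at the published
per-group first-picture rates. The distributional *forms* are conventions
— only means/SDs are published — and the trend archetypes default to slope
±0.005 rating units/picture with noise SD 0.15 over 30–100 pictures, the
regime in which the slope t-test has non-trivial (≈ 89%) power.

Two generator choices matter for testability:

- **Ratings are mean-exact.** A picture's intended mean is
  clip(baseline + slope·(k−1) + noise, 0, 1); the n individual ratings are
  uniform perturbations recentred (and, near the 0/1 ends, rescaled) so
  their empirical mean equals the target exactly while every value stays
  in [0, 1]. Downstream analyses consume only the mean and count, so this
  sacrifices nothing and makes label-recovery tests exact.
- **Timestamps are whole-second exact.** The first and last picture are
  placed exactly one drawn period apart, so an intended Active can never
  be rounded below the 7-day bound.

The Active archetype draws ≥ 12 pictures so that the validity rule (which
removes at most two) cannot demote an intended Active. With the validity
rule disabled (all rating counts ≥ 10, no test first pictures), pipeline
classification recovers archetype intent *exactly*; with the default ~4%
test-first rate, a Non-active occasionally becomes a Non-user — that
interference is the behaviour under study, not an error.

What the generator does **not** emulate: real attrition dynamics (e.g.
weekday-dependent registration unless configured), rater-level biases and
nonstationary rating standards, picture content, social-network structure
in likes/comments, or the non-linear score displayed in-app. Passing tests
therefore validate the pipeline's logic and calibration, not claims about
any real population.

## Problem sizes and numerical tolerances

Oracle-equivalence checks (chi-square, ANOVA, OLS slope vs brute-force
summation) run on 1,000 random instances at ≤ 1e-9 relative disagreement
(measured ≈ 1e-16). Calibration checks use 1,000 zero-slope users × 30
pictures × 10 seeds for the type-I rate (±1.5 pp band around 5%), 1,500
generated Improvers against a 6,000-replicate Monte-Carlo power oracle
(±3 pp band), and 500 replicate homogeneous grids for family-wise control
(≤ 5%); these sizes keep the whole suite under a minute of statistical
simulation while leaving 2.5–7 σ of margin on every band.
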