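# dietcohort

Cohort analysis of usage logs from photographic dietary self-monitoring
apps — tools for asking "who keeps using the app, and does their eating
improve?" from nothing but raw event tables.

The package is aimed at mHealth and behavioural-epidemiology researchers
working with app telemetry: users photograph their meals, rate them on a
0 ("fat") to 1 ("fit") healthiness scale, and receive crowdsourced peer
ratings, likes, and comments. From five flat CSV event tables (users,
pictures, ratings, likes, comments) the pipeline produces:

- **Adherence classification.** Each user's non-empty pictures are screened
  by a validity rule (a first or second picture with fewer than 10 peer
  ratings is treated as a test shot and excluded; later pictures are never
  examined), then classified: *Non-user* (no valid pictures), *Non-active*
  (one), *Semi-active* (≥ 2 but fewer than 10 pictures or under a week of
  use), *Active* (≥ 10 pictures over ≥ 7 days). Non-users and Non-actives
  together are *Dropouts*; the rest are *Users*.
- **Initiation context.** Registration times are binned on a 7 × 5 weekday
  × daypart grid (night/morning/daytime/late afternoon/evening) and each
  cell is tested for Users-vs-Dropouts enrichment with a 2 × 2 Pearson
  chi-square at the Bonferroni-corrected level α/35 ≈ .0014.
- **Dietary preference and peer feedback.** Onboarding "How do you eat?"
  answers map to NotDefined / Everything / Strict / Other; proportions
  across categories and adherence groups are compared with uncorrected
  Pearson 2 × k chi-square tests and Tukey-type multiple comparisons of
  proportions (arcsine-square-root transform, studentized range).
- **Healthiness trends.** For each eligible Active user, the mean peer
  rating of picture *k* is regressed on the index *k* = 1…N by OLS; a
  significant (two-sided *P* < .05) positive slope marks an *Improver*,
  negative a *Decliner*. Improvers are compared to other Actives with
  pooled two-sample *t* tests on usage activity.

Because real app datasets of this kind are proprietary, the package ships a
synthetic cohort generator (`dietcohort.simulate`) that draws users from
adherence archetypes with configurable picture-count, usage-period, rating,
and engagement laws — every analysis stage is testable end to end against
known ground truth.

## Worked example

```python
import dietcohort as dc

config = dc.CohortConfig(
    n_per_archetype={"NonUser": 600, "NonActive": 250, "SemiActive": 110,
                     "Active": 25, "ActiveImprover": 10, "ActiveDecliner": 5},
    seed=20,
)
cohort = dc.generate_cohort(config)
bundle = dc.run_pipeline(cohort)

print(bundle.tables["adherence"][["activity_level", "count", "pct"]].to_string(index=False))
print(bundle.tables["trend_counts"].to_string(index=False))
res = bundle.tests["first_picture_description"]
print(f"description presence chi2({res.df[0]:.0f}) = {res.statistic:.1f}, p = {res.p_value:.3g}")
```

prints

```
activity_level  count  pct
       NonUser    612 61.2
     NonActive    238 23.8
    SemiActive    110 11.0
        Active     40  4.0
classification  count
      Improver     10
      Decliner      5
       NoTrend     25
description presence chi2(2) = 21.9, p = 1.78e-05
```

The adherence counts differ slightly from the archetype quotas because the
validity rule fires on some first pictures (a Non-active whose single
picture is a low-rated test shot becomes a Non-user); all 10 built-in
Improvers were detected, and the description-presence chi-square picks up
the higher engagement rate of the Active archetypes.

The same workflow is available from the shell:

```bash
dietcohort simulate --seed 42 --out cohort/
dietcohort analyze --in cohort/ --out report/   # CSV tables + summary.txt
dietcohort report --in cohort/ --out report/    # also prints the summary
```

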