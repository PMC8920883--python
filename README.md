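# factorscreen

Exhaustive factorial subgroup screening for categorical cohorts.

Epidemiological effects are rarely uniform: the association between a
binary exposure (say, low vs. high socioeconomic status) and a binary
outcome (say, current asthma) can be amplified or reversed inside
subgroups such as "girls aged 11–13" or "children of young mothers".
`factorscreen` makes that heterogeneity visible by brute force: it
enumerates **every** subgroup defined by one factor level or by a pair of
levels from two distinct factors, estimates the effect in each, and
presents the results so that striking subgroups can be judged by people,
not p-values.  It is aimed at epidemiologists and biostatisticians doing
hypothesis-generating analyses of survey or registry cohorts.

## The statistic

Within a subgroup *S*, with `a`/`b` the cases in the index/reference
exposure arm and `c`/`d` the non-cases (controls), the screen reports the
crude odds ratio and its Wald interval

```
OR(S) = (a·d) / (b·c),       CI = exp( ln OR ± z · √(1/a + 1/b + 1/c + 1/d) )
```

or, alternatively, the crude outcome proportion `(a+b)/(a+b+c+d)`.
Cases of a *different* outcome are excluded from the table, so screens of
mutually exclusive outcomes stay disjoint.  A catalogue with per-factor
level counts `l₁…lₚ` yields `Σlᵢ + Σᵢ<ⱼ lᵢlⱼ` subgroups at depth 2 — e.g.
221 levels over 56 factors give 22,704 subgroups, screened in about one
second.  Degenerate tables are encoded (0, ∞, undefined), never dropped;
extreme values are truncated only for display (defaults 0.3 and 15).

Around the core screen the package provides:

* **funnel / comparison / trend views** — subgroup size vs. estimate
  around the overall reference; two outcomes side by side; level-wise
  estimates of ordered factors with a strict-monotonicity verdict;
* **random-forest triage** (`RandomForestImportance`, `fit_forest`) —
  OOB-error grid search, permutation importance (VIMP) and minimal
  depth, plus a bias-corrected Cramér's V filter for redundant factors;
* **follow-up models** (`fit_logistic`, `stepwise_select`) —
  multivariable logistic regression with exposure interactions and
  hierarchy-aware AIC-stepwise selection (forward/backward/both), each
  fit tested against the intercept-only model;
* **a synthetic-cohort generator** (`simulate_cohort`) with plantable
  exposure×factor interactions and exact implied ground-truth odds
  ratios, so every stage is testable without restricted survey data.

## Worked example

Plant a decreasing exposure-interaction trend over an ordered
"mother's age" factor and screen it back out:

```python
import math
from factorscreen import (Factor, FactorCatalog, PlantedEffect, SimConfig,
                          SubgroupScreener, simulate_cohort)

cat = FactorCatalog((
    Factor("mother_age", ("<=24", "25-29", "30-34", ">=35"), is_ordered=True),
    Factor("sex", ("boy", "girl")),
))
cfg = SimConfig(
    n_subjects=20_000, catalog=cat, outcome_names=("asthma",),
    baseline_log_odds={"asthma": math.log(0.017 / 0.983)},
    exposure_log_or={"asthma": math.log(1.68)},
    planted=(PlantedEffect(outcome="asthma", factor="mother_age",
                           interaction_trend=(1.0, -0.7)),),
    seed=7,
)
cohort, truth = simulate_cohort(cfg)

screener = SubgroupScreener(depth=2).fit(cohort)
print(len(screener.results_))                             # 14
print(round(float(screener.overall_.loc["asthma", "point"]), 2))  # 1.92
report = screener.interaction_trend("mother_age", "asthma")
print([round(e, 2) for e in report.estimates])  # [4.02, 2.59, 0.99, 0.3]
print(report.monotone_direction)                # decreasing
```

The 2×4 catalogue yields 14 subgroup rows (6 singles + 8 pairs).  The
overall screened OR is 1.92 — the exposure's marginal effect, inflated
above the planted baseline of 1.68 by the young-mother interaction.  The
trend view reads the four age-level ORs in ordinal order, 4.02 down to
0.30, and labels the trend `decreasing`; the generator's ground truth for
those levels was (4.57, 2.27, 1.13, 0.56), so the screen recovered both
the ordering and the approximate magnitudes.  The same workflow is
available from the shell:

```sh
factorscreen simulate --n 4686 --seed 17 --out cohort.csv --catalog-out catalog.yaml
factorscreen screen --cohort cohort.csv --catalog catalog.yaml --depth 2 \
    --out results/ --plots
factorscreen importance --cohort cohort.csv --catalog catalog.yaml \
    --outcome rhinitis --out imp/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the worked-example catalogues, enumerates their subgroups from
scratch with the package's enumeration engine, cross-checks the counts
against the closed form, runs one full simulate-and-screen pass at the
given seed, and writes the counted quantities as JSON.
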