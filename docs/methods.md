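# Methods

This note records the statistical model behind `factorscreen`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions a reader would need
to reproduce or audit a run.

## The screening model

The unit of analysis is the *subgroup*: the subjects satisfying a
conjunction of `factor=level` constraints, at most one constraint per
factor, with depth capped at 2 by default.  Deeper subgroups are
supported but off by default: they overlap heavily, get very small, and
are hard to interpret.  Enumeration is exhaustive and independent of the
cohort — an empty subgroup is still a row, flagged `empty`, so result
tables have a stable shape across cohorts.

For each subgroup and each outcome the screen builds the 2×2 table of
cases vs. common controls by exposure arm.  "Common controls" means
subjects with *no* outcome present; cases of a different outcome are
excluded from the table.  With three mutually exclusive outcomes this
yields three disjoint case-control analyses that cannot contaminate each
other through overlapping case groups.

The default statistic is the crude odds ratio `ad/bc` with a Wald
interval on the log scale.  Degenerate tables are encoded rather than
raised or corrected:

| table | point | flags |
|---|---|---|
| `b·c = 0`, `a·d > 0` | `inf` | `zero_cell, infinite` |
| `a·d = 0`, `b·c > 0` | `0` | `zero_cell` |
| `a·d = b·c = 0` | `NaN` | `undefined` |

No continuity correction is applied by default (a Haldane–Anscombe-style
+0.5 can be added by the caller building tables); extreme values are kept
in the results and clamped only in the `display_point` column, by default
into [0.3, 15].  The same odds ratio is available through an iteratively
reweighted logistic fit of `outcome ~ exposure`; for a single binary
covariate the model is saturated, so the exponentiated slope equals the
cross-product ratio — the test suite enforces agreement to 1e-6 relative
error, which guards both code paths.

Deliberately, subgroup rows carry **no p-values and no multiplicity
adjustment**.  The screen is a hypothesis-generating overview; attaching
22,704 p-values would invite exactly the dichotomised reading the design
avoids.  CI columns exist for calibration checks and whole-cohort
summaries; the "striking" judgement is left to inspection of the funnel,
comparison and trend views, supported by the `top_subgroups` ordering
(|log display value| relative to the overall reference).

The trend view applies only to factors declared ordered.  Its verdict is
strict: `decreasing` requires every consecutive pair to strictly
decrease; ties or any non-finite estimate give `none`.  The reserved
`"no data"` level never enters a trend sequence — missingness is not a
point on an ordinal scale.

## Data model and cleaning

Input is one CSV row per subject (UTF-8, comma-separated, header
required; empty strings and `NA` read as missing) plus a YAML/JSON
catalogue of factors and levels.  Exclusion rules (raw exposure levels to
drop, columns whose missingness drops the row, an optional predicate
filter) are applied in declared order with first-match attribution, so
the per-rule tally is deterministic and sums to `rows_in − rows_out`.
After exclusions, remaining missing *factor* values may be recoded to the
explicit level `"no data"`, which keeps systematic missingness visible as
its own subgroup instead of silently shrinking others.  Numeric columns
are binned into right-closed classes (`cut[i-1] < v ≤ cut[i]`); the
convention matters for integer-valued variables like age and is fixed
here once.

## Synthetic cohorts

`simulate_cohort` draws factors independently from declared marginals
(uniform by default), a Bernoulli exposure (index-arm probability 0.325
by default — the low-SES fraction of the motivating survey), and one
outcome category per subject from a multinomial logit over
{outcome₁, …, none} with per-outcome log-odds

```
eta_k = baseline_k + exposure_lor_k·I(index) + main(levels) + I(index)·interaction(levels)
```

Baselines are calibrated so the default prevalences are ≈1.7%, 7.7% and
1.5% — the asthma-only / rhinitis-only / both-diseases pattern of a large
cross-sectional allergy survey.  Because "none" is the control category,
the implied conditional OR inside a subgroup is exactly
`exp(exposure_lor + active interaction terms)`; the generator emits these
closed-form values as ground truth, so recovery tests need no second
simulator.  The default catalogue has 56 factors with level counts
[58, 7, 5, 3×45, 2×8] — the unique totals with Σl = 221 and Σl² = 3875,
hence 22,704 depth-2 subgroups; the 58-level factor is structural (it
exists to satisfy the count identity), and the 3/5/7-level factors are
flagged ordered as plausible ordinal class scales.  The default cohort
size is 4686, the analysis N of the motivating survey.

What the generator does **not** emulate: real marginal distributions of
named survey variables, dependence between factors (an optional hook
aside, factors are independent), survey weights, and informative
missingness (`inject_missing` blanks completely at random).  A green
recovery test therefore establishes that the pipeline detects planted
effects under clean conditions, not that it would rank real-world
confounded factors correctly.

One calibration note: the null-cohort false-striking rate (share of large
depth-1 subgroups whose 95% CI excludes 1 under no planted effects) is
estimated pooled over 20 replicate cohorts.  Within one cohort the 221
depth-1 subgroups share the same case pool, so their intervals are
strongly correlated and a single-cohort rate ranges roughly 0–20% by
chance; the pooled estimate sits at the nominal ~5%.

## Forest triage

The factor ranking uses a bootstrap ensemble of scikit-learn decision
trees over ordinal-coded factors, with the bootstrap, OOB bookkeeping,
permutation importance and minimal depth implemented in the package
(per-tree in-bag membership is needed and not exposed by stock forest
classes).  Conventions:

* **nsplit** maps to randomised splitting (`splitter="random"`, one
  random threshold per candidate feature) for any value ≥ 1 and to
  exhaustive best-split search for `None`/0.  A literal "k random cut
  candidates per factor" rule is not expressible with the underlying
  trees; this approximation preserves the intent (cheap, randomised,
  weakly greedy splits) and is the one documented behaviour.
* **VIMP** is the average over trees of (tree's OOB error after permuting
  one factor's OOB values − its baseline OOB error).  A factor used by no
  tree scores exactly 0; values near or below zero indicate noise.
* **Minimal depth** of a factor in a tree is the depth of its shallowest
  split (root = 0); a factor absent from a tree scores that tree's
  maximal depth + 1 (a documented convention — some convention is needed
  and "deepest possible + 1" penalises absence monotonically).  The
  selection threshold is the expected minimal depth under uninformative
  split assignment: visiting the tree's m internal nodes in depth order
  `d₍₁₎ ≤ … ≤ d₍ₘ₎`, a given factor first appears at node j with
  probability `(1−1/p)^(j−1)/p`, so the per-tree expectation is
  `Σⱼ d₍ⱼ₎ (1−1/p)^(j−1)/p + (D+1)(1−1/p)^m`, averaged over trees.
  Factors below the threshold are marked selected.
* The grid search (`fit_forest`) trains on an 80% split, selects the
  (nodesize, nsplit, mtry) combination with the lowest OOB error (ties:
  smaller nodesize, then smaller mtry), and reports the 20% held-out
  error of the winner.  Defaults nodesize 10, nsplit 2, mtry 3 follow the
  motivating analysis; the ensemble size (default 300 trees; 100 in the
  heavier simulation studies) is a package choice, as the source analyses
  do not state one.
* Rows with missing factor values are omitted listwise, not imputed, and
  the correlation pre-filter (bias-corrected Cramér's V, threshold 0.9,
  drop the factor with more levels) runs before fitting.  Both the
  association measure and the threshold are package choices — only the
  existence of a correlation-based exclusion step is inherited.

All randomness (bootstrap, tree seeds, permutations, the 80/20 split)
derives from one seed via `numpy` `SeedSequence` spawning, so identical
configurations reproduce exactly.

## Follow-up models

`fit_logistic` fits `outcome ~ exposure + factors + exposure:factors` by
Newton maximum likelihood (statsmodels; relative tolerance 1e-8, max 100
iterations) on the outcome's case/common-control universe, with
treatment coding against explicitly declared reference levels.  Rank
deficiency raises an error naming the aliased terms; separation (fit
failure or |coefficient| > 15) is flagged and a weakly ridge-regularised
fit is reported in its place so the trace stays inspectable.  Every fit
reports the AIC (`−2·loglik + 2·parameters`, asserted as an identity in
tests) and a likelihood-ratio test against the intercept-only model on
the same rows (closed form: the null intercept is the empirical log-odds).

Stepwise selection is greedy single-move AIC descent, stopping when no
move improves, with ties broken by candidate declaration order and
non-convergent candidate fits skipped with a warning.  The hierarchy rule
(interactions enter after, and leave before, their main effects) is
enforced; it is the conventional choice and keeps every visited model
interpretable.  Greedy search can in principle miss the global AIC
optimum; the test suite checks agreement with an exhaustive search over
small candidate lattices, where disagreement is rare but allowed.

## Known limitations

* The screen is crude by design: no adjustment, no weighting, no
  within-subgroup confounder control.  It finds candidates, not effects.
* Wald intervals misbehave at very small cell counts; such subgroups are
  flagged (`zero_cell`) rather than corrected.
* The forest operates on ordinal-coded factors, so nominal factors with
  many levels are split as if ordered — adequate for triage, not for
  interpretation of split points.
* Determinism is guaranteed per platform and dependency set; floating
  point results may differ in the last bits across BLAS builds.
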