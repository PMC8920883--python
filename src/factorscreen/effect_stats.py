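"""Per-subgroup effect statistics: odds ratios, Wald intervals, proportions.

The screening statistic is the crude odds ratio of a binary exposure on a
binary outcome inside one subgroup, computed from the 2x2 table

    =============  ======  ==========
                   cases   non-cases
    index arm        a         c
    reference arm    b         d
    =============  ======  ==========

as ``OR = (a*d) / (b*c)``; an OR above 1 means higher odds of the outcome
in the index arm.  Degenerate tables are encoded, never raised: a zero
denominator with a positive numerator is ``inf``, a zero numerator is 0,
and 0/0 is undefined (NaN, flagged).  No continuity correction is applied
by default — extreme values are kept and only *truncated for display*
(defaults 0.3 and 15), with the raw point always preserved.

The same OR is available through an iteratively reweighted logistic fit
(``logistic_or``); on non-degenerate tables the exponentiated slope of
``outcome ~ exposure`` equals the closed form exactly (saturated binary
model), which serves as a numerical cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "TwoByTwoTable",
    "EffectEstimate",
    "TruncationConfig",
    "crosstab",
    "odds_ratio",
    "wald_ci",
    "logistic_or",
    "crude_proportion",
    "truncate_display",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts within one subgroup.

    ``a``/``c``: cases/non-cases in the index-exposure arm;
    ``b``/``d``: cases/non-cases in the reference arm.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def swap_arms(self) -> "TwoByTwoTable":
        """Exchange index and reference arms (maps OR to 1/OR)."""
        return TwoByTwoTable(a=self.b, b=self.a, c=self.d, d=self.c)


@dataclass(frozen=True)
class TruncationConfig:
    """Display clamp for extreme odds ratios (raw values are kept)."""

    trunc_low: float = 0.3
    trunc_high: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.trunc_low < self.trunc_high):
            raise ValueError("need 0 < trunc_low < trunc_high")


@dataclass(frozen=True)
class EffectEstimate:
    """One subgroup estimate: raw point, Wald CI, n, display value, flags.

    ``point`` may be ``inf`` (flag ``infinite``) or NaN (flag ``undefined``);
    the CI is NaN whenever any 2x2 cell is zero (flag ``zero_cell``).
    ``display_point`` is the truncated value used in funnel plots.
    """

    kind: str  # "odds_ratio" | "proportion"
    point: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    display_point: float = math.nan
    flags: tuple[str, ...] = ()
    table: TwoByTwoTable | None = None

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.point)


def crosstab(cohort, subgroup, outcome: str, control_def=None) -> TwoByTwoTable:
    """Exposure-by-outcome 2x2 table inside a subgroup.

    Cases are subjects with ``outcome == yes``; controls default to the
    common control group (no outcome present).  Subjects that are neither —
    cases of a *different* outcome — are excluded from the table, keeping
    the three disease screens disjoint.
    """
    from .enumeration import member_mask  # local import avoids a cycle

    sg = member_mask(subgroup, cohort) if subgroup is not None else np.ones(cohort.n, bool)
    case = cohort.case_mask(outcome)
    control = control_def(cohort) if control_def is not None else cohort.control_mask()
    index = cohort.exposure_index_mask()
    return TwoByTwoTable(
        a=int((sg & case & index).sum()),
        b=int((sg & case & ~index).sum()),
        c=int((sg & control & index).sum()),
        d=int((sg & control & ~index).sum()),
    )


def odds_ratio(table: TwoByTwoTable) -> EffectEstimate:
    """Cross-product odds ratio with degenerate cases encoded, not raised."""
    num = table.a * table.d
    den = table.b * table.c
    flags: list[str] = []
    if table.is_empty:
        flags.append("empty")
    if table.has_zero_cell and not table.is_empty:
        flags.append("zero_cell")
    if den > 0:
        point = num / den
    elif num > 0:
        point = math.inf
        flags.append("infinite")
    else:
        point = math.nan
        flags.append("undefined")
    return EffectEstimate(
        kind="odds_ratio", point=point, n=table.n, flags=tuple(flags), table=table
    )


def wald_ci(table: TwoByTwoTable, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval on the log-odds-ratio scale.

    ``exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  Undefined (NaN, NaN)
    when any cell is zero.
    """
    if table.has_zero_cell:
        return (math.nan, math.nan)
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log((table.a * table.d) / (table.b * table.c))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def estimate_odds_ratio(
    table: TwoByTwoTable, level: float = 0.95
) -> EffectEstimate:
    """Odds ratio plus Wald CI as one estimate record."""
    est = odds_ratio(table)
    lo, hi = wald_ci(table, level)
    return replace(est, ci_low=lo, ci_high=hi)


def logistic_or(
    case: np.ndarray,
    index_arm: np.ndarray,
    level: float = 0.95,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> EffectEstimate:
    """Odds ratio from an iteratively reweighted logistic regression fit.

    Fits ``case ~ intercept + index_arm`` by maximum likelihood and returns
    the exponentiated slope with its Wald interval.  With a single binary
    covariate the model is saturated, so the result equals the closed-form
    cross-product OR; this routine exists to honour that identity with an
    independent code path.  Tables with a zero cell produce complete or
    quasi-complete separation: these are detected up front and fall back to
    the closed-form degenerate encoding with a ``separation`` flag.
    """
    import statsmodels.api as sm

    case = np.asarray(case, dtype=bool)
    index_arm = np.asarray(index_arm, dtype=bool)
    table = TwoByTwoTable(
        a=int((case & index_arm).sum()),
        b=int((case & ~index_arm).sum()),
        c=int((~case & index_arm).sum()),
        d=int((~case & ~index_arm).sum()),
    )
    if index_arm.all() or not index_arm.any():
        est = odds_ratio(table)
        return replace(est, point=math.nan, flags=est.flags + ("single_arm",))
    if table.has_zero_cell:
        est = estimate_odds_ratio(table, level)
        return replace(est, flags=est.flags + ("separation",))
    # aggregate to the four table rows; frequency weights keep the fit exact
    y = np.array([1.0, 1.0, 0.0, 0.0])
    x = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    w = np.array([table.a, table.b, table.c, table.d], dtype=float)
    model = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(tol=tol, maxiter=maxiter)
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = stats.norm.ppf(0.5 + level / 2.0)
    flags = () if res.converged else ("non_converged",)
    return EffectEstimate(
        kind="odds_ratio",
        point=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        n=table.n,
        flags=flags,
        table=table,
    )


def crude_proportion(n_cases: int, n_controls: int) -> EffectEstimate:
    """Crude outcome proportion ``cases / (cases + controls)`` in a subset.

    The denominator is the subgroup's case+control universe, ignoring the
    exposure split.  Empty denominator is undefined.
    """
    denom = n_cases + n_controls
    if denom == 0:
        return EffectEstimate(
            kind="proportion", point=math.nan, n=0, flags=("empty", "undefined")
        )
    return EffectEstimate(kind="proportion", point=n_cases / denom, n=denom)


def truncate_display(
    estimate: EffectEstimate, cfg: TruncationConfig | None = None
) -> EffectEstimate:
    """Clamp the point into ``[trunc_low, trunc_high]`` for display only.

    ``inf`` maps to the upper bound and 0/undefined to the lower bound; the
    stored point and CI are untouched.  Idempotent.
    """
    cfg = cfg or TruncationConfig()
    flags = tuple(f for f in estimate.flags if f != "truncated")
    p = estimate.point
    if estimate.kind != "odds_ratio":
        return replace(estimate, display_point=p, flags=flags)
    if math.isnan(p):
        disp = cfg.trunc_low
        flags += ("truncated",)
    elif p > cfg.trunc_high:
        disp = cfg.trunc_high
        flags += ("truncated",)
    elif p < cfg.trunc_low:
        disp = cfg.trunc_low
        flags += ("truncated",)
    else:
        disp = p
    return replace(estimate, display_point=disp, flags=flags)
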