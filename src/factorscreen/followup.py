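"""Follow-up multivariable logistic models with exposure interactions.

Screening generates hypotheses; this module is the "further
investigation" step for the factors judged striking: a multivariable
logistic regression of one outcome (cases vs. the common control group)
on the exposure, selected factors, and factor-by-exposure interactions,
with treatment (reference-level) dummy coding against explicitly declared
reference levels.

Model search is greedy AIC-stepwise in three directions — forward from
the exposure-only base model, backward from the full model, or
bidirectional — under the usual hierarchy rule: an interaction may enter
only while its main effect is present, and a main effect may leave only
after its interaction.  Every reported model carries a likelihood-ratio
test against the intercept-only model fitted on the same rows.

Estimation is delegated to statsmodels (Newton ML, relative tolerance
1e-8, at most 100 iterations); the term bookkeeping, hierarchy-aware
stepwise search and the reporting layer live here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .catalog import CohortTable, FactorCatalog

logger = logging.getLogger(__name__)

#: A candidate model term: ("main", factor) or ("interaction", factor).
Term = tuple[str, str]


@dataclass(frozen=True)
class ModelSpec:
    """One logistic model: outcome, main effects, exposure interactions.

    ``references`` maps factor name to its reference level (default: the
    factor's first declared level).  Every interaction factor must also
    appear as a main effect.
    """

    outcome: str
    main_effects: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    references: dict = field(default_factory=dict)
    include_exposure: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_effects", tuple(self.main_effects))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        missing = set(self.interactions) - set(self.main_effects)
        if missing:
            raise ValueError(
                f"interaction factors lack main effects: {sorted(missing)}"
            )

    def reference_for(self, factor, catalog: FactorCatalog) -> str:
        ref = self.references.get(factor, catalog[factor].levels[0])
        if ref not in catalog[factor].levels:
            raise ValueError(f"reference {ref!r} is not a level of {factor!r}")
        return ref

    def terms(self) -> list[Term]:
        return [("main", f) for f in self.main_effects] + [
            ("interaction", f) for f in self.interactions
        ]

    def with_terms(self, terms: list[Term]) -> "ModelSpec":
        mains = tuple(f for k, f in terms if k == "main")
        inters = tuple(f for k, f in terms if k == "interaction")
        return replace(self, main_effects=mains, interactions=inters)


@dataclass
class FitResult:
    """A fitted logistic model and its reporting surface.

    ``coef_table`` has one row per estimated parameter: term label,
    coefficient, OR = exp(coefficient), Wald 95% CI (on the OR scale) and
    nominal p-value.  ``lr_stat``/``lr_pvalue`` test the model against the
    intercept-only model on the same rows.
    """

    spec: ModelSpec
    coef_table: pd.DataFrame
    loglik: float
    aic: float
    n: int
    n_params: int
    null_loglik: float
    lr_stat: float
    lr_pvalue: float
    converged: bool
    flags: tuple[str, ...] = ()
    n_dropped_missing: int = 0


def build_design(
    cohort: CohortTable, spec: ModelSpec, catalog: FactorCatalog | None = None
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Treatment-coded design matrix and response for one model.

    Rows are the outcome's case+control universe (cases of the outcome
    vs. subjects with no outcome at all); rows missing any model term are
    dropped listwise and counted.  Returns ``(X, y, n_dropped)``.
    """
    catalog = catalog if catalog is not None else cohort.catalog
    case = cohort.case_mask(spec.outcome)
    control = cohort.control_mask()
    universe = case | control
    df = cohort.data.loc[universe]
    y_all = case[universe]

    used_cols = list(dict.fromkeys(spec.main_effects))
    keep = np.ones(len(df), dtype=bool)
    for col in used_cols:
        keep &= df[col].notna().to_numpy()
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    y = y_all[keep].astype(float)

    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    expo = (df[cohort.exposure] == cohort.index_label).astype(float)
    if spec.include_exposure:
        X[f"exposure[{cohort.index_label}]"] = expo
    for fac in spec.main_effects:
        ref = spec.reference_for(fac, catalog)
        for lv in catalog[fac].levels:
            if lv == ref:
                continue
            X[f"{fac}[{lv}]"] = (df[fac] == lv).astype(float)
    for fac in spec.interactions:
        ref = spec.reference_for(fac, catalog)
        for lv in catalog[fac].levels:
            if lv == ref:
                continue
            X[f"exposure:{fac}[{lv}]"] = expo * (df[fac] == lv).astype(float)
    # drop dummies that are identically zero (level absent from these rows)
    nonzero = [c for c in X.columns if c == "Intercept" or X[c].abs().sum() > 0]
    X = X[nonzero]
    return X, np.asarray(y), n_dropped


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the aliased columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {bad}")


def fit_logistic(
    cohort: CohortTable,
    spec: ModelSpec,
    catalog: FactorCatalog | None = None,
    *,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FitResult:
    """Maximum-likelihood logistic fit of one :class:`ModelSpec`.

    Separation (diverging coefficients or non-convergence) is detected
    and flagged, not raised.  The AIC identity ``-2 loglik + 2 k`` holds
    for every returned fit.
    """
    import statsmodels.api as sm

    catalog = catalog if catalog is not None else cohort.catalog
    X, y, n_dropped = build_design(cohort, spec, catalog)
    if n_dropped:
        logger.info("fit_logistic: dropped %d rows with missing terms", n_dropped)
    _check_rank(X)
    flags: list[str] = []

    model = sm.Logit(y, X.to_numpy())
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation raises in statsmodels
            res = None
            converged = False
    if res is None:
        flags.append("separation")
        # refit with a tiny ridge so a usable (flagged) fit is still reported
        res = model.fit_regularized(alpha=1e-6, disp=0, maxiter=200)
    elif not converged:
        flags.append("non_converged")
    elif np.abs(res.params).max() > 15:
        flags.append("separation")
        converged = False

    params = np.asarray(res.params)
    try:
        bse = np.asarray(res.bse)
    except Exception:
        bse = np.full_like(params, np.nan)
    z = stats.norm.ppf(0.975)
    pvals = 2 * stats.norm.sf(np.abs(params / bse))
    coef_table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": params,
            "or": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvals,
        }
    )
    loglik = float(res.llf)
    k = X.shape[1]
    aic = -2.0 * loglik + 2.0 * k

    # intercept-only model on the same rows has a closed-form solution
    p_hat = y.mean()
    null_loglik = float(
        len(y) * (p_hat * math.log(p_hat) + (1 - p_hat) * math.log(1 - p_hat))
        if 0 < p_hat < 1
        else 0.0
    )
    lr = max(0.0, 2.0 * (loglik - null_loglik))
    df_diff = k - 1
    lr_p = float(stats.chi2.sf(lr, df_diff)) if df_diff > 0 else 1.0
    return FitResult(
        spec=spec,
        coef_table=coef_table,
        loglik=loglik,
        aic=aic,
        n=len(y),
        n_params=k,
        null_loglik=null_loglik,
        lr_stat=lr,
        lr_pvalue=lr_p if df_diff > 0 else 1.0,
        converged=converged,
        flags=tuple(flags),
        n_dropped_missing=n_dropped,
    )


def lr_test_vs_null(fit: FitResult) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value vs. the intercept-only model."""
    return fit.lr_stat, fit.lr_pvalue


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------


def _valid_additions(current: list[Term], candidates: list[Term]) -> list[Term]:
    out = []
    mains = {f for k, f in current if k == "main"}
    for t in candidates:
        if t in current:
            continue
        if t[0] == "interaction" and t[1] not in mains:
            continue  # hierarchy: main effect must already be in
        out.append(t)
    return out


def _valid_removals(current: list[Term]) -> list[Term]:
    inters = {f for k, f in current if k == "interaction"}
    out = []
    for t in current:
        if t[0] == "main" and t[1] in inters:
            continue  # hierarchy: interactions leave first
        out.append(t)
    return out


def stepwise_select(
    cohort: CohortTable,
    base_spec: ModelSpec,
    candidates: list[Term],
    direction: str = "forward",
    catalog: FactorCatalog | None = None,
) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Greedy AIC-stepwise model selection.

    ``direction`` is ``forward`` (start from ``base_spec``, usually
    exposure-only), ``backward`` (start from the full candidate model) or
    ``both`` (adds and drops considered at every step, starting like
    forward).  At each step the single move with the lowest resulting AIC
    is taken; the search stops when no move lowers the AIC.  Ties break by
    candidate declaration order.  Candidate fits that fail to converge are
    skipped with a logged warning.  Returns the selected spec, its fit and
    the full trace (step, action, term, AIC).
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    catalog = catalog if catalog is not None else cohort.catalog

    if direction == "backward":
        current = list(base_spec.terms()) + [
            t for t in candidates if t not in base_spec.terms()
        ]
    else:
        current = list(base_spec.terms())

    def fit_terms(terms: list[Term]) -> FitResult | None:
        try:
            return fit_logistic(cohort, base_spec.with_terms(terms), catalog)
        except Exception as exc:
            logger.warning("skipping candidate %s: %s", terms, exc)
            return None

    cur_fit = fit_terms(current)
    if cur_fit is None:
        raise RuntimeError("the starting model did not fit")
    trace_rows = [
        {"step": 0, "action": "start", "term": "", "aic": cur_fit.aic}
    ]
    order = {t: i for i, t in enumerate(candidates)}

    step = 0
    while True:
        step += 1
        moves: list[tuple[str, Term]] = []
        if direction in ("forward", "both"):
            moves += [("add", t) for t in _valid_additions(current, candidates)]
        if direction in ("backward", "both"):
            moves += [("drop", t) for t in _valid_removals(current)]

        best: tuple[float, int, str, Term, list[Term], FitResult] | None = None
        for action, term in moves:
            terms = current + [term] if action == "add" else [
                t for t in current if t != term
            ]
            fit = fit_terms(terms)
            if fit is None or not fit.converged:
                if fit is not None and not fit.converged:
                    logger.warning("skipping non-convergent move %s %s", action, term)
                continue
            key = (fit.aic, order.get(term, len(order)))
            if best is None or key < (best[0], best[1]):
                best = (fit.aic, order.get(term, len(order)), action, term, terms, fit)

        if best is None or best[0] >= cur_fit.aic - 1e-12:
            break
        _, _, action, term, current, cur_fit = best
        trace_rows.append(
            {"step": step, "action": action, "term": f"{term[0]}:{term[1]}",
             "aic": cur_fit.aic}
        )

    trace = pd.DataFrame(trace_rows)
    return base_spec.with_terms(current), cur_fit, trace


class StepwiseLogistic(BaseEstimator):
    """Estimator facade over :func:`stepwise_select`.

    Parameters mirror the function; after ``fit(cohort)`` the selected
    spec, its :class:`FitResult` and the AIC trace are available as
    ``spec_``, ``fit_result_`` and ``trace_``.
    """

    def __init__(
        self,
        outcome: str = "",
        candidates: list[Term] | None = None,
        direction: str = "forward",
        references: dict | None = None,
    ):
        self.outcome = outcome
        self.candidates = candidates
        self.direction = direction
        self.references = references

    def fit(self, cohort: CohortTable, catalog: FactorCatalog | None = None):
        base = ModelSpec(
            outcome=self.outcome or cohort.outcomes[0],
            references=self.references or {},
        )
        candidates = self.candidates or [
            ("main", f) for f in cohort.factor_columns
        ]
        self.spec_, self.fit_result_, self.trace_ = stepwise_select(
            cohort, base, candidates, self.direction, catalog
        )
        return self

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        """Fitted event probabilities for the cohort's case/control rows."""
        if not hasattr(self, "fit_result_"):
            raise RuntimeError("call fit() first")
        X, _, _ = build_design(cohort, self.spec_)
        beta = self.fit_result_.coef_table.set_index("term")["estimate"]
        eta = X.to_numpy() @ beta.reindex(X.columns).fillna(0.0).to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])
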