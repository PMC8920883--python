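"""Seeded synthetic survey cohorts with plantable subgroup effects.

The generator emulates the structure the screening assumes: a catalogue of
categorical factors, a binary exposure (index arm ~32.5% by default, the
low-SES fraction of the motivating survey), and three mutually exclusive
binary outcomes drawn from one multinomial over {outcome_1, ..., none}
whose per-outcome log-odds (against "none") are

    eta_k = baseline_k + exposure_lor_k * I(index arm)
            + main_effect(factor levels) + I(index arm) * interaction(levels)

Because "none" is the common control group, the true conditional odds
ratio (cases of outcome k vs. controls, index vs. reference arm) inside a
subgroup is exactly ``exp(exposure_lor_k + sum of interaction terms active
in that subgroup)`` — the generator emits these implied values as ground
truth so recovery tests need no second simulator.

Default prevalences are calibrated to roughly 1.7% / 7.7% / 1.5% for the
three outcomes, matching a large cross-sectional allergy survey; the
default catalogue (:func:`kiggs_like_default`) has 56 factors whose level
counts sum to 221 with a sum of squares of 3875, so depth-2 enumeration
yields exactly 22,704 subgroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Factor, FactorCatalog, CohortTable, NODATA_LEVEL
from .enumeration import Subgroup

#: Default outcome prevalences (fractions of the whole cohort).
DEFAULT_PREVALENCES = {"asthma": 0.017, "rhinitis": 0.077, "both": 0.015}


def calibrated_baselines(prevalences: Mapping[str, float]) -> dict[str, float]:
    """Multinomial-logit baselines reproducing the target prevalences.

    With no covariate effects, ``P(k) = exp(b_k) / (1 + sum_j exp(b_j))``,
    so ``b_k = ln(p_k / p_none)``.
    """
    p_none = 1.0 - sum(prevalences.values())
    if p_none <= 0:
        raise ValueError("prevalences must sum to < 1")
    return {k: math.log(p / p_none) for k, p in prevalences.items()}


@dataclass(frozen=True)
class PlantedEffect:
    """A factor (or factor-pair) effect planted on one outcome.

    ``main_log_odds`` shifts the outcome's log-odds in both exposure arms;
    ``interaction_log_odds`` shifts it in the index arm only — this is the
    exposure-by-factor interaction the screen must detect.  Keys are level
    labels (tuples of labels for a factor pair).  ``interaction_trend``
    ``(intercept, slope)`` is a shorthand expanding to a linear-in-position
    interaction over the factor's ordered levels ("no data" excluded).
    """

    outcome: str
    factor: str | tuple[str, str]
    main_log_odds: Mapping = field(default_factory=dict)
    interaction_log_odds: Mapping = field(default_factory=dict)
    interaction_trend: tuple[float, float] | None = None

    def expanded_interaction(self, catalog: FactorCatalog) -> dict:
        """Per-level interaction log-odds with any trend shorthand expanded."""
        out = dict(self.interaction_log_odds)
        if self.interaction_trend is not None:
            if not isinstance(self.factor, str):
                raise ValueError("interaction_trend applies to single factors only")
            icpt, slope = self.interaction_trend
            for i, lv in enumerate(catalog[self.factor].trend_levels()):
                out[lv] = out.get(lv, 0.0) + icpt + slope * i
        return out


@dataclass
class SimConfig:
    """Full generative description of a synthetic cohort."""

    n_subjects: int
    catalog: FactorCatalog
    outcome_names: tuple[str, ...] = ("asthma", "rhinitis", "both")
    baseline_log_odds: dict[str, float] | None = None
    exposure_log_or: dict[str, float] = field(default_factory=dict)
    exposure_p_index: float = 0.325
    index_label: str = "low"
    reference_label: str = "high"
    level_probs: dict[str, Sequence[float]] = field(default_factory=dict)
    planted: tuple[PlantedEffect, ...] = ()
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outcome_names = tuple(self.outcome_names)
        self.planted = tuple(self.planted)
        if self.baseline_log_odds is None:
            prev = {k: DEFAULT_PREVALENCES.get(k, 0.05) for k in self.outcome_names}
            self.baseline_log_odds = calibrated_baselines(prev)
        if not 0.0 <= self.exposure_p_index <= 1.0:
            raise ValueError("exposure_p_index must be a probability")
        for fac, p in self.level_probs.items():
            p = np.asarray(p, float)
            if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
                raise ValueError(f"level_probs for {fac!r} must be a distribution")
        for r in self.missing_rates.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")
        for eff in self.planted:
            facs = (eff.factor,) if isinstance(eff.factor, str) else eff.factor
            for f in facs:
                if f not in self.catalog:
                    raise ValueError(f"planted effect factor {f!r} not in catalogue")
            if eff.outcome not in self.outcome_names:
                raise ValueError(f"planted effect outcome {eff.outcome!r} unknown")


def kiggs_like_default(n_subjects: int = 4686, seed: int = 0) -> SimConfig:
    """Default survey-like configuration: 56 factors, 221 levels in total.

    Level counts are one 58-level factor, one 7-level, one 5-level,
    forty-five 3-level and eight 2-level factors — the unique totals with
    ``sum(l) = 221`` and ``sum(l^2) = 3875``, so the depth-2 subgroup count
    is 221 + (221^2 - 3875)/2 = 22,704.  The 58-level factor is structural
    (it exists to satisfy the count identity, think of a fine-grained
    region code), not substantive.  Exposure marginal 0.325; baselines
    calibrated to the default prevalences; no planted effects.
    """
    counts = [58, 7, 5] + [3] * 45 + [2] * 8
    factors = []
    for i, k in enumerate(counts, start=1):
        factors.append(
            Factor(
                name=f"x{i:02d}",
                levels=tuple(f"L{j}" for j in range(1, k + 1)),
                is_ordered=k in (3, 5, 7),  # ordinal class scales
            )
        )
    return SimConfig(n_subjects=n_subjects, catalog=FactorCatalog(tuple(factors)), seed=seed)


def _factor_probs(cfg: SimConfig, fac: Factor) -> np.ndarray:
    if fac.name in cfg.level_probs:
        return np.asarray(cfg.level_probs[fac.name], float)
    return np.full(fac.n_levels, 1.0 / fac.n_levels)


def simulate_cohort(cfg: SimConfig) -> tuple[CohortTable, dict]:
    """Draw a synthetic cohort; return it with its ground-truth record.

    Factors are drawn independently per declared marginals, the exposure is
    Bernoulli, and the outcome category comes from the multinomial logit
    described in the module docstring.  Missingness is applied last and
    never touches exposure or outcomes.  Identical configs (including the
    seed) give byte-identical cohorts.

    The ground-truth record maps each subgroup touched by a planted
    interaction (and each overall outcome) to its implied conditional odds
    ratio, computed in closed form from the generative log-odds.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    codes: dict[str, np.ndarray] = {}
    columns: dict[str, object] = {}
    for fac in cfg.catalog:
        p = _factor_probs(cfg, fac)
        if len(p) != fac.n_levels:
            raise ValueError(f"level_probs for {fac.name!r} has wrong length")
        c = rng.choice(fac.n_levels, size=n, p=p)
        codes[fac.name] = c
        columns[fac.name] = np.asarray(fac.levels, dtype=object)[c]

    index_arm = rng.random(n) < cfg.exposure_p_index

    # per-outcome linear predictors against the "none" reference category
    eta = {
        k: np.full(n, cfg.baseline_log_odds[k])
        + cfg.exposure_log_or.get(k, 0.0) * index_arm
        for k in cfg.outcome_names
    }
    for eff in cfg.planted:
        inter = eff.expanded_interaction(cfg.catalog)
        if isinstance(eff.factor, str):
            levels = np.asarray(cfg.catalog[eff.factor].levels, dtype=object)
            vals = levels[codes[eff.factor]]
            for lv, lor in eff.main_log_odds.items():
                eta[eff.outcome][vals == lv] += lor
            for lv, lor in inter.items():
                eta[eff.outcome][(vals == lv) & index_arm] += lor
        else:
            f1, f2 = eff.factor
            l1 = np.asarray(cfg.catalog[f1].levels, dtype=object)[codes[f1]]
            l2 = np.asarray(cfg.catalog[f2].levels, dtype=object)[codes[f2]]
            for (a, b), lor in eff.main_log_odds.items():
                eta[eff.outcome][(l1 == a) & (l2 == b)] += lor
            for (a, b), lor in inter.items():
                eta[eff.outcome][(l1 == a) & (l2 == b) & index_arm] += lor

    expeta = np.column_stack([np.exp(eta[k]) for k in cfg.outcome_names])
    denom = 1.0 + expeta.sum(axis=1)
    probs = expeta / denom[:, None]  # columns: outcomes; residual mass = none
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    # category index: number of cumulative bounds below u (== len -> "none")
    cat = (u[:, None] >= cum).sum(axis=1)

    df = pd.DataFrame({"subject_id": np.arange(1, n + 1).astype(str)})
    df["exposure"] = np.where(index_arm, cfg.index_label, cfg.reference_label)
    for j, k in enumerate(cfg.outcome_names):
        df[k] = np.where(cat == j, "yes", "no")
    for fac in cfg.catalog:
        df[fac.name] = columns[fac.name]

    cohort = CohortTable(
        data=df,
        catalog=cfg.catalog,
        exposure="exposure",
        outcomes=cfg.outcome_names,
        subject_id="subject_id",
        index_label=cfg.index_label,
        reference_label=cfg.reference_label,
    )
    if any(r > 0 for r in cfg.missing_rates.values()):
        cohort = inject_missing(
            cohort, cfg.missing_rates, seed=int(rng.integers(2**31))
        )

    truth: dict = {"overall": {}, "subgroups": {}}
    for k in cfg.outcome_names:
        truth["overall"][k] = math.exp(cfg.exposure_log_or.get(k, 0.0))
    for eff in cfg.planted:
        inter = eff.expanded_interaction(cfg.catalog)
        base = cfg.exposure_log_or.get(eff.outcome, 0.0)
        if isinstance(eff.factor, str):
            for lv in cfg.catalog[eff.factor].levels:
                sg = Subgroup(((eff.factor, lv),))
                truth["subgroups"].setdefault(sg.key, {})[eff.outcome] = math.exp(
                    base + inter.get(lv, 0.0)
                )
        else:
            f1, f2 = eff.factor
            for l1 in cfg.catalog[f1].levels:
                for l2 in cfg.catalog[f2].levels:
                    sg = Subgroup(((f1, l1), (f2, l2)))
                    truth["subgroups"].setdefault(sg.key, {})[eff.outcome] = math.exp(
                        base + inter.get((l1, l2), 0.0)
                    )
    return cohort, truth


def inject_missing(
    cohort: CohortTable, rates: Mapping[str, float], seed: int = 0
) -> CohortTable:
    """Blank each factor value independently with its per-factor rate.

    Exposure and outcome columns are never blanked by this operation.
    """
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    for fac, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {fac!r} outside [0, 1]")
        if rate == 0.0 or fac not in df.columns:
            continue
        mask = rng.random(len(df)) < rate
        col = df[fac].astype(object)
        col[mask] = np.nan
        df[fac] = col
    return cohort.copy(data=df)
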