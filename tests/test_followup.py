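"""Follow-up logistic models: fitting, AIC identity, stepwise vs. brute force."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from factorscreen import (
    CohortTable,
    Factor,
    FactorCatalog,
    ModelSpec,
    PlantedEffect,
    SimConfig,
    StepwiseLogistic,
    fit_logistic,
    lr_test_vs_null,
    stepwise_select,
)
from factorscreen.followup import build_design
from factorscreen import simulate_cohort


def make_sim(n=5000, seed=0, planted=(), factors=3):
    cat = FactorCatalog(
        tuple(Factor(f"f{i}", ("a", "b")) for i in range(factors))
    )
    return SimConfig(
        n_subjects=n,
        catalog=cat,
        outcome_names=("disease",),
        baseline_log_odds={"disease": math.log(0.1 / 0.9)},
        exposure_log_or={"disease": 0.3},
        planted=tuple(planted),
        seed=seed,
    )


def exhaustive_aic_search(cohort, base_spec, candidates):
    """Brute-force oracle: fit every hierarchy-valid term subset, pick min AIC."""
    best = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            mains = {f for k, f in subset if k == "main"}
            if any(k == "interaction" and f not in mains for k, f in subset):
                continue
            fit = fit_logistic(cohort, base_spec.with_terms(list(subset)))
            if best is None or fit.aic < best[1]:
                best = (set(subset), fit.aic)
    return best


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        """Intercept of the null model is the empirical log-odds ln(78/4175)."""
        n_case, n_ctrl = 78, 4175
        df = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(n_case + n_ctrl)],
                "exposure": "high",
                "disease": ["yes"] * n_case + ["no"] * n_ctrl,
                "f0": "a",
            }
        )
        cat = FactorCatalog((Factor("f0", ("a", "b")),))
        cohort = CohortTable(data=df, catalog=cat, outcomes=("disease",))
        spec = ModelSpec(outcome="disease", include_exposure=False)
        fit = fit_logistic(cohort, spec)
        icpt = fit.coef_table.set_index("term").loc["Intercept", "estimate"]
        assert icpt == pytest.approx(math.log(n_case / n_ctrl), rel=1e-6)
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-8)
        assert fit.lr_pvalue == 1.0

    def test_binary_covariate_matches_crossproduct(self):
        """Saturated-model identity shared with the screening statistic."""
        cohort, _ = simulate_cohort(make_sim(seed=1))
        spec = ModelSpec(outcome="disease")
        fit = fit_logistic(cohort, spec)
        beta = fit.coef_table.set_index("term").loc["exposure[low]", "estimate"]
        from factorscreen import crosstab, odds_ratio

        t = crosstab(cohort, None, "disease")
        closed = odds_ratio(t).point
        assert abs(math.exp(beta) - closed) / closed <= 1e-6

    def test_aic_identity(self):
        cohort, _ = simulate_cohort(make_sim(seed=2))
        spec = ModelSpec(
            outcome="disease", main_effects=("f0", "f1"), interactions=("f0",)
        )
        fit = fit_logistic(cohort, spec)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_interaction_recovery(self):
        """Planted exposure interaction ln(OR)=1 recovered within +-0.15."""
        eff = PlantedEffect(
            outcome="disease", factor="f0", interaction_log_odds={"b": 1.0}
        )
        cohort, _ = simulate_cohort(make_sim(n=20_000, seed=3, planted=[eff]))
        spec = ModelSpec(
            outcome="disease", main_effects=("f0",), interactions=("f0",),
            references={"f0": "a"},
        )
        fit = fit_logistic(cohort, spec)
        coef = fit.coef_table.set_index("term").loc["exposure:f0[b]", "estimate"]
        assert abs(coef - 1.0) <= 0.15

    def test_rank_deficiency_names_terms(self):
        cohort, _ = simulate_cohort(make_sim(n=500, seed=4))
        cohort.data["f1"] = cohort.data["f0"]  # aliased factor
        spec = ModelSpec(outcome="disease", main_effects=("f0", "f1"))
        with pytest.raises(ValueError, match="aliased"):
            fit_logistic(cohort, spec)

    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="disease", interactions=("f0",))

    def test_lr_reference_level_invariance(self):
        cohort, _ = simulate_cohort(make_sim(seed=5))
        fit_a = fit_logistic(
            cohort,
            ModelSpec(outcome="disease", main_effects=("f0",), references={"f0": "a"}),
        )
        fit_b = fit_logistic(
            cohort,
            ModelSpec(outcome="disease", main_effects=("f0",), references={"f0": "b"}),
        )
        assert lr_test_vs_null(fit_a)[0] == pytest.approx(
            lr_test_vs_null(fit_b)[0], abs=1e-6
        )

    def test_design_universe_excludes_other_cases(self):
        cat = FactorCatalog((Factor("f0", ("a", "b")),))
        df = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(6)],
                "exposure": ["low", "high"] * 3,
                "d1": ["yes", "no", "no", "no", "no", "no"],
                "d2": ["no", "yes", "no", "no", "no", "no"],
                "f0": ["a"] * 6,
            }
        )
        cohort = CohortTable(data=df, catalog=cat, outcomes=("d1", "d2"))
        X, y, _ = build_design(cohort, ModelSpec(outcome="d1"))
        assert len(y) == 5  # the d2 case is excluded from d1's universe


class TestStepwise:
    def test_forward_finds_true_term_and_matches_oracle(self):
        eff = PlantedEffect(
            outcome="disease", factor="f0", main_log_odds={"b": 0.9}
        )
        cohort, _ = simulate_cohort(make_sim(n=5000, seed=6, planted=[eff]))
        base = ModelSpec(outcome="disease")
        candidates = [("main", "f0"), ("main", "f1"), ("main", "f2")]
        spec, fit, trace = stepwise_select(cohort, base, candidates, "forward")
        oracle_terms, oracle_aic = exhaustive_aic_search(cohort, base, candidates)
        assert set(spec.terms()) == oracle_terms
        assert fit.aic == pytest.approx(oracle_aic)
        assert "main:f0" in set(trace["term"])

    def test_backward_agrees_with_forward(self):
        eff = PlantedEffect(
            outcome="disease", factor="f0", main_log_odds={"b": 0.9}
        )
        cohort, _ = simulate_cohort(make_sim(n=5000, seed=6, planted=[eff]))
        base = ModelSpec(outcome="disease")
        candidates = [("main", "f0"), ("main", "f1"), ("main", "f2")]
        fwd, fit_f, _ = stepwise_select(cohort, base, candidates, "forward")
        bwd, fit_b, _ = stepwise_select(cohort, base, candidates, "backward")
        assert set(fwd.terms()) == set(bwd.terms())
        assert fit_f.aic == pytest.approx(fit_b.aic)

    def test_null_data_mostly_stops_at_base(self):
        """Empty-signal cohorts: forward selection usually keeps no term.

        A pure-noise candidate still enters when its chi2(1) deviance gain
        exceeds 2 (prob. ~0.157), so the base model is the *typical*, not
        certain, endpoint; over seeds the selected noise count must stay
        near its null expectation.
        """
        n_kept = []
        for seed in range(6):
            cohort, _ = simulate_cohort(make_sim(n=4000, seed=100 + seed))
            base = ModelSpec(outcome="disease", include_exposure=False)
            candidates = [("main", f"f{i}") for i in range(3)]
            spec, fit, trace = stepwise_select(cohort, base, candidates, "forward")
            n_kept.append(len(spec.terms()))
        assert sum(k == 0 for k in n_kept) >= 2  # base model is common
        assert np.mean(n_kept) <= 1.5            # and noise entry stays rare

    def test_hierarchy_interaction_needs_main(self):
        eff = PlantedEffect(
            outcome="disease", factor="f0", interaction_log_odds={"b": 1.2}
        )
        cohort, _ = simulate_cohort(make_sim(n=10_000, seed=8, planted=[eff]))
        base = ModelSpec(outcome="disease")
        candidates = [
            ("interaction", "f0"),  # declared before its main effect
            ("main", "f0"),
            ("main", "f1"),
        ]
        spec, fit, trace = stepwise_select(cohort, base, candidates, "both")
        if "f0" in spec.interactions:
            assert "f0" in spec.main_effects  # hierarchy held at every step
        added = list(trace["term"])
        if "interaction:f0" in added:
            assert added.index("main:f0") < added.index("interaction:f0")

    def test_estimator_facade(self):
        eff = PlantedEffect(
            outcome="disease", factor="f0", main_log_odds={"b": 0.9}
        )
        cohort, _ = simulate_cohort(make_sim(n=4000, seed=9, planted=[eff]))
        est = StepwiseLogistic(
            outcome="disease",
            candidates=[("main", "f0"), ("main", "f1")],
            direction="forward",
        ).fit(cohort)
        assert "f0" in est.spec_.main_effects
        proba = est.predict_proba(cohort)
        assert proba.shape[1] == 2
        assert np.all((proba >= 0) & (proba <= 1))

    def test_strong_effect_lr_significant(self):
        eff = PlantedEffect(
            outcome="disease", factor="f0", main_log_odds={"b": 1.5}
        )
        cohort, _ = simulate_cohort(make_sim(n=5000, seed=10, planted=[eff]))
        fit = fit_logistic(
            cohort, ModelSpec(outcome="disease", main_effects=("f0",))
        )
        assert fit.lr_pvalue < 0.001
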