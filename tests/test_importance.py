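"""Forest-based factor triage: correlation filter, OOB, VIMP, minimal depth."""

import math

import numpy as np
import pandas as pd
import pytest

from factorscreen import (
    CohortTable,
    Factor,
    FactorCatalog,
    ForestConfig,
    PlantedEffect,
    RandomForestImportance,
    SimConfig,
    correlation_filter,
    cramers_v,
    fit_forest,
    simulate_cohort,
)


def signal_config(n=3000, seed=0, log_or=math.log(5.0), n_noise=5):
    """One informative 2-level factor among independent noise factors."""
    cat = FactorCatalog(
        (Factor("signal", ("risk", "safe")),)
        + tuple(Factor(f"noise{i}", ("a", "b", "c")) for i in range(n_noise))
    )
    eff = PlantedEffect(
        outcome="disease", factor="signal", main_log_odds={"risk": log_or}
    )
    return SimConfig(
        n_subjects=n,
        catalog=cat,
        outcome_names=("disease",),
        baseline_log_odds={"disease": math.log(0.15 / 0.85)},
        planted=(eff,),
        seed=seed,
    )


class TestCorrelationFilter:
    def _cohort(self, df_cols: dict, levels: dict):
        cat = FactorCatalog(
            tuple(Factor(n, tuple(lv)) for n, lv in levels.items())
        )
        df = pd.DataFrame(df_cols)
        df.insert(0, "exposure", "low")
        df.insert(0, "subject_id", [str(i) for i in range(len(df))])
        return CohortTable(data=df, catalog=cat)

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.choice(["a", "b"], 400)
        cohort = self._cohort(
            {"f1": x, "f2": x.copy()}, {"f1": ["a", "b"], "f2": ["a", "b"]}
        )
        retained, dropped, v = correlation_filter(cohort, threshold=0.9)
        assert retained == ["f1"]
        assert dropped[0][:2] == ("f1", "f2")
        assert v.loc["f1", "f2"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_factors_not_dropped(self):
        rng = np.random.default_rng(2)
        cols = {f"f{i}": rng.choice(["a", "b", "c"], 2000) for i in range(4)}
        cohort = self._cohort(cols, {k: ["a", "b", "c"] for k in cols})
        retained, dropped, _ = correlation_filter(cohort, threshold=0.9)
        assert len(retained) == 4 and not dropped

    def test_triple_duplicate_keeps_one(self):
        rng = np.random.default_rng(3)
        x = rng.choice(["a", "b"], 300)
        cohort = self._cohort(
            {"f1": x, "f2": x.copy(), "f3": x.copy()},
            {k: ["a", "b"] for k in ("f1", "f2", "f3")},
        )
        retained, dropped, _ = correlation_filter(cohort, threshold=0.9)
        assert len(retained) == 1 and len(dropped) == 2

    def test_more_levels_dropped_first(self):
        rng = np.random.default_rng(4)
        fine = rng.choice(["a", "b", "c", "d"], 500)
        coarse = np.where(np.isin(fine, ["a", "b"]), "lo", "hi")
        cohort = self._cohort(
            {"fine": fine, "coarse": coarse},
            {"fine": ["a", "b", "c", "d"], "coarse": ["lo", "hi"]},
        )
        retained, dropped, _ = correlation_filter(cohort, threshold=0.8)
        assert retained == ["coarse"]

    def test_corrected_v_near_zero_for_independent(self):
        rng = np.random.default_rng(5)
        a = pd.Series(rng.choice(["x", "y"], 2000))
        b = pd.Series(rng.choice(["u", "v", "w"], 2000))
        assert cramers_v(a, b) < 0.1

    def test_threshold_validated(self, small_cohort):
        with pytest.raises(ValueError):
            correlation_filter(small_cohort, threshold=0.0)


class TestForestFit:
    def test_pure_noise_oob_near_half(self):
        rng = np.random.default_rng(6)
        n = 1500
        X = pd.DataFrame({f"f{i}": rng.choice(["a", "b", "c"], n) for i in range(5)})
        y = rng.choice(["yes", "no"], n)
        forest = RandomForestImportance(
            n_trees=100, nodesize=10, nsplit=2, mtry=3, random_state=0
        ).fit(X, y)
        assert 0.45 <= forest.oob_error_ <= 0.55

    def test_perfect_signal_oob_near_zero(self):
        rng = np.random.default_rng(7)
        n = 1500
        X = pd.DataFrame({f"f{i}": rng.choice(["a", "b"], n) for i in range(4)})
        y = np.where(X["f0"] == "a", "yes", "no")
        forest = RandomForestImportance(
            n_trees=100, nodesize=10, nsplit=2, mtry=2, random_state=0
        ).fit(X, y)
        assert forest.oob_error_ <= 0.02

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(8)
        n = 800
        X = pd.DataFrame({f"f{i}": rng.choice(["a", "b"], n) for i in range(3)})
        y = rng.choice(["yes", "no"], n)
        f1 = RandomForestImportance(n_trees=50, random_state=5).fit(X, y)
        f2 = RandomForestImportance(n_trees=50, random_state=5).fit(X, y)
        assert f1.oob_error_ == f2.oob_error_
        pd.testing.assert_series_equal(f1.vimp_, f2.vimp_)
        pd.testing.assert_series_equal(f1.minimal_depth_, f2.minimal_depth_)

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"f": ["a", "b"] * 10})
        with pytest.raises(ValueError):
            RandomForestImportance(n_trees=5).fit(X, np.repeat("no", 20))


class TestVimp:
    def test_planted_predictor_ranks_first(self):
        cohort, _ = simulate_cohort(signal_config(seed=10))
        res = fit_forest(
            cohort,
            outcome="disease",
            cfg=ForestConfig(n_trees=100, mtry_grid=(3,), seed=10),
        )
        assert res.vimp.idxmax() == "signal"
        assert res.vimp["signal"] > 0

    def test_noise_vimp_near_zero(self):
        cohort, _ = simulate_cohort(signal_config(seed=11))
        res = fit_forest(
            cohort, outcome="disease",
            cfg=ForestConfig(n_trees=100, seed=11),
        )
        noise = res.vimp.drop("signal")
        assert np.abs(noise).max() < 0.02

    def test_unused_factor_vimp_exactly_zero(self):
        # with mtry covering all features and a dominant signal, a constant
        # factor is never split on and must score exactly 0
        rng = np.random.default_rng(12)
        n = 500
        X = pd.DataFrame(
            {
                "sig": rng.choice(["a", "b"], n),
                "const": ["z"] * n,
            }
        )
        y = np.where(X["sig"] == "a", "yes", "no")
        forest = RandomForestImportance(
            n_trees=30, nodesize=5, nsplit=None, mtry=2, random_state=0
        ).fit(X, y)
        assert forest.vimp_["const"] == 0.0


class TestMinimalDepth:
    def test_root_split_factor_depth_zero(self):
        rng = np.random.default_rng(13)
        n = 600
        X = pd.DataFrame(
            {
                "sig": rng.choice(["a", "b"], n),
                "noise": rng.choice(["a", "b"], n),
            }
        )
        y = np.where(X["sig"] == "a", "yes", "no")
        forest = RandomForestImportance(
            n_trees=40, nodesize=5, nsplit=None, mtry=1, random_state=1
        ).fit(X, y)
        # the informative factor is (almost) always the effective root split
        assert forest.minimal_depth_["sig"] < forest.minimal_depth_["noise"]

    def test_planted_predictor_smallest_depth_and_agrees_with_vimp(self):
        cohort, _ = simulate_cohort(signal_config(seed=14))
        res = fit_forest(
            cohort, outcome="disease", cfg=ForestConfig(n_trees=100, seed=14)
        )
        assert res.minimal_depth.idxmin() == "signal"
        assert res.vimp.idxmax() == res.minimal_depth.idxmin()

    def test_relabeling_outcome_invariant(self):
        rng = np.random.default_rng(15)
        n = 600
        X = pd.DataFrame({f"f{i}": rng.choice(["a", "b"], n) for i in range(3)})
        y = rng.choice(["yes", "no"], n)
        f1 = RandomForestImportance(n_trees=40, random_state=3).fit(X, y)
        swap = np.where(y == "yes", "no", "yes")
        f2 = RandomForestImportance(n_trees=40, random_state=3).fit(X, swap)
        pd.testing.assert_series_equal(f1.minimal_depth_, f2.minimal_depth_)

    def test_threshold_between_zero_and_absent_score(self):
        cohort, _ = simulate_cohort(signal_config(seed=16))
        res = fit_forest(
            cohort, outcome="disease", cfg=ForestConfig(n_trees=50, seed=16)
        )
        assert 0 < res.minimal_depth_threshold < res.minimal_depth.max() + 1


class TestGridSearch:
    def test_selected_config_minimises_oob(self):
        cohort, _ = simulate_cohort(signal_config(n=2000, seed=17))
        res = fit_forest(
            cohort,
            outcome="disease",
            cfg=ForestConfig(
                n_trees=60,
                nodesize_grid=(5, 20),
                mtry_grid=(2, 4),
                seed=17,
            ),
        )
        assert res.oob_error == res.grid["oob_error"].min()
        assert len(res.grid) == 4

    def test_missing_rows_omitted(self):
        from factorscreen import inject_missing

        cohort, _ = simulate_cohort(signal_config(n=1500, seed=18))
        holey = inject_missing(cohort, {"noise0": 0.2}, seed=18)
        res = fit_forest(
            holey, outcome="disease", cfg=ForestConfig(n_trees=30, seed=18)
        )
        assert res.forest is not None  # listwise deletion, fit still works
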