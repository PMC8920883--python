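"""Factor triage by a randomised tree ensemble: VIMP, minimal depth, OOB.

The screen itself deliberately reports no p-values, so a second,
model-based ranking of the factors is useful to cross-check which ones
carry predictive signal for an outcome.  This module grows a bootstrap
ensemble of randomised classification trees over the categorical factors
and derives:

* **OOB error** — misclassification of each subject by the trees that did
  not see it (the bootstrap's built-in cross-validation), also the
  criterion for the hyperparameter grid search;
* **VIMP** (permutation variable importance) — the average over trees of
  the increase in that tree's out-of-bag error after permuting one
  factor's OOB values; positive values mark informative factors, values
  near or below zero mark noise;
* **minimal depth** — the average depth of the first split on a factor
  (root = 0; a factor absent from a tree scores that tree's maximal depth
  plus one); factors that partition large sample fractions sit near the
  root.  The selection threshold is the expected minimal depth if split
  variables were assigned uniformly at random to the observed tree
  shapes (see :meth:`RandomForestImportance.minimal_depth_threshold_`).

Tree induction is delegated to scikit-learn's ``DecisionTreeClassifier``;
the bootstrap, OOB bookkeeping, permutation importance and depth
statistics are implemented here because they need per-tree in-bag
membership.  Rows with missing factor values are omitted, not imputed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier

from .catalog import CohortTable, FactorCatalog


# ---------------------------------------------------------------------------
# Correlation pre-filter
# ---------------------------------------------------------------------------


def cramers_v(x: pd.Series, y: pd.Series, corrected: bool = True) -> float:
    """Cramér's V between two categorical columns (bias-corrected by default).

    The correction (Bergsma) subtracts the expected chance association
    ``(k-1)(r-1)/(n-1)`` from phi^2 and shrinks the table dimensions
    accordingly, so independent columns score near 0 even at modest n.
    """
    ok = x.notna() & y.notna()
    tab = pd.crosstab(x[ok], y[ok]).to_numpy()
    n = tab.sum()
    if n == 0 or min(tab.shape) < 2:
        return 0.0
    chi2 = sps.chi2_contingency(tab, correction=False)[0]
    phi2 = chi2 / n
    r, k = tab.shape
    if corrected:
        phi2 = max(0.0, phi2 - (k - 1) * (r - 1) / (n - 1))
        r = r - (r - 1) ** 2 / (n - 1)
        k = k - (k - 1) ** 2 / (n - 1)
    denom = min(k - 1, r - 1)
    return float(np.sqrt(phi2 / denom)) if denom > 0 else 0.0


def correlation_filter(
    cohort: CohortTable,
    catalog: FactorCatalog | None = None,
    threshold: float = 0.9,
) -> tuple[list[str], list[tuple[str, str, float]], pd.DataFrame]:
    """Drop one factor of every highly associated pair before forest fitting.

    Returns ``(retained, dropped_pairs, matrix)``: the retained factor
    names, the ``(kept, dropped, V)`` decisions, and the full pairwise
    bias-corrected Cramér's V matrix for a correlogram.  From each pair
    with V above the threshold the factor with more levels is dropped
    (tie: the one later in catalogue order); applied greedily from the
    strongest pair down, so mutually duplicated triples lose two members.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    catalog = catalog if catalog is not None else cohort.catalog
    names = [f.name for f in catalog if f.name in cohort.data.columns]
    v = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pairs = []
    for a, b in itertools.combinations(names, 2):
        val = cramers_v(cohort.data[a], cohort.data[b])
        v.loc[a, b] = v.loc[b, a] = val
        pairs.append((val, a, b))
    pairs.sort(key=lambda t: (-t[0], names.index(t[1]), names.index(t[2])))

    retained = list(names)
    dropped: list[tuple[str, str, float]] = []
    for val, a, b in pairs:
        if val < threshold or a not in retained or b not in retained:
            continue
        ka, kb = catalog[a].n_levels, catalog[b].n_levels
        if ka > kb or (ka == kb and names.index(a) > names.index(b)):
            keep, drop = b, a
        else:
            keep, drop = a, b
        retained.remove(drop)
        dropped.append((keep, drop, val))
    return retained, dropped, v


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


class RandomForestImportance(BaseEstimator):
    """Bootstrap ensemble of randomised trees over categorical factors.

    Parameters
    ----------
    n_trees : int
        Ensemble size.
    nodesize : int
        Minimum samples per leaf.
    nsplit : int or None
        Randomised splitting: any value >= 1 selects random split points
        (one random threshold per candidate feature); None/0 selects the
        best split exhaustively.
    mtry : int
        Number of candidate factors per split.
    random_state : int
        One seed drives the bootstrap, the per-tree split randomness and
        the VIMP permutations (documented substream derivation), so runs
        are exactly reproducible.

    Attributes (after ``fit``)
    --------------------------
    oob_error_ : float
        Out-of-bag misclassification rate of the ensemble vote.
    vimp_ : pandas.Series
        Signed permutation importance per factor.
    minimal_depth_ : pandas.Series
        Mean minimal depth per factor.
    minimal_depth_threshold_ : float
        Expected mean minimal depth under uninformative split assignment.
    """

    def __init__(
        self,
        n_trees: int = 300,
        nodesize: int = 10,
        nsplit: int | None = 2,
        mtry: int = 3,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.nodesize = nodesize
        self.nsplit = nsplit
        self.mtry = mtry
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(X), len(self.feature_names_)), dtype=np.float64)
        for j, name in enumerate(self.feature_names_):
            cat = pd.Categorical(X[name], categories=self.categories_[name])
            codes = cat.codes.astype(np.float64)
            if (codes < 0).any():
                raise ValueError(f"unseen or missing level in column {name!r}")
            out[:, j] = codes
        return out

    def fit(self, X: pd.DataFrame, y):
        """Fit the ensemble on categorical features ``X`` and binary ``y``.

        Rows with missing values must already have been removed (see
        :func:`fit_forest`, which does listwise deletion).
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("outcome has a single class; nothing to learn")
        self.feature_names_ = list(X.columns)
        self.categories_ = {
            c: sorted(X[c].dropna().unique()) for c in self.feature_names_
        }
        Xc = self._encode(X)
        n, p = Xc.shape
        ss = np.random.SeedSequence(self.random_state)
        boot_rng = np.random.default_rng(ss.spawn(1)[0])
        tree_seeds = np.random.default_rng(ss.spawn(2)[1]).integers(
            2**31, size=self.n_trees
        )

        splitter = "random" if self.nsplit else "best"
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []
        votes = np.zeros((n, len(self.classes_)), dtype=np.int64)
        for t in range(self.n_trees):
            idx = boot_rng.integers(n, size=n)
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            tree = DecisionTreeClassifier(
                splitter=splitter,
                max_features=min(self.mtry, p),
                min_samples_leaf=self.nodesize,
                random_state=int(tree_seeds[t]),
            )
            tree.fit(Xc[idx], y_enc[idx])
            self.trees_.append(tree)
            self.inbag_.append(inbag)
            oob = ~inbag
            if oob.any():
                pred = tree.predict(Xc[oob]).astype(np.int64)
                votes[np.flatnonzero(oob), pred] += 1

        voted = votes.sum(axis=1) > 0
        oob_pred = votes.argmax(axis=1)
        self.oob_error_ = float(np.mean(oob_pred[voted] != y_enc[voted]))
        self._Xc = Xc
        self._y = y_enc
        self._vimp_rng_seed = ss.spawn(3)[2]
        self.vimp_ = self._compute_vimp()
        self.minimal_depth_, self.minimal_depth_threshold_ = self._compute_minimal_depth()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority vote of the ensemble."""
        Xc = self._encode(pd.DataFrame(X))
        votes = np.zeros((len(Xc), len(self.classes_)), dtype=np.int64)
        for tree in self.trees_:
            pred = tree.predict(Xc).astype(np.int64)
            votes[np.arange(len(Xc)), pred] += 1
        return self.classes_[votes.argmax(axis=1)]

    # -- importance measures --------------------------------------------

    def _compute_vimp(self) -> pd.Series:
        """Average over trees of (permuted OOB error - baseline OOB error)."""
        rng = np.random.default_rng(self._vimp_rng_seed)
        p = len(self.feature_names_)
        total = np.zeros(p)
        for tree, inbag in zip(self.trees_, self.inbag_):
            oob = np.flatnonzero(~inbag)
            if len(oob) == 0:
                continue
            Xoob = self._Xc[oob]
            yoob = self._y[oob]
            base_err = np.mean(tree.predict(Xoob) != yoob)
            used = set(tree.tree_.feature[tree.tree_.feature >= 0])
            for j in range(p):
                if j not in used:
                    continue  # permuting an unused factor changes nothing
                perm = rng.permutation(len(oob))
                Xp = Xoob.copy()
                Xp[:, j] = Xoob[perm, j]
                total[j] += np.mean(tree.predict(Xp) != yoob) - base_err
        return pd.Series(total / self.n_trees, index=self.feature_names_, name="vimp")

    def _tree_depths(self, tree: DecisionTreeClassifier) -> tuple[np.ndarray, np.ndarray]:
        """Per-node depth and split-feature arrays (leaves get feature -2)."""
        t = tree.tree_
        depth = np.zeros(t.node_count, dtype=np.int64)
        stack = [(0, 0)]
        while stack:
            node, d = stack.pop()
            depth[node] = d
            if t.children_left[node] != -1:
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        return depth, t.feature

    def _compute_minimal_depth(self) -> tuple[pd.Series, float]:
        """Mean minimal depth per factor and its null-expectation threshold.

        A factor absent from a tree scores that tree's maximal depth + 1.
        The threshold averages, over trees, the expected minimal depth of a
        single factor when the tree's internal nodes (visited in depth
        order) each pick their split variable uniformly among the p
        factors: ``sum_j d_(j) (1-1/p)^(j-1)/p + (D+1)(1-1/p)^m``.
        """
        p = len(self.feature_names_)
        md_sum = np.zeros(p)
        thr_sum = 0.0
        for tree in self.trees_:
            depth, feature = self._tree_depths(tree)
            internal = feature >= 0
            max_depth = int(depth.max())
            md = np.full(p, max_depth + 1, dtype=np.float64)
            for node in np.flatnonzero(internal):
                f = feature[node]
                if depth[node] < md[f]:
                    md[f] = depth[node]
            md_sum += md
            d_sorted = np.sort(depth[internal])
            m = len(d_sorted)
            if m and p > 0:
                q = 1.0 - 1.0 / p
                w = q ** np.arange(m) / p
                thr_sum += float((d_sorted * w).sum() + (max_depth + 1) * q**m)
            else:
                thr_sum += max_depth + 1
        md_mean = pd.Series(
            md_sum / self.n_trees, index=self.feature_names_, name="minimal_depth"
        )
        return md_mean, thr_sum / self.n_trees


# ---------------------------------------------------------------------------
# Grid search on the 80/20 split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameter grid and split for :func:`fit_forest`."""

    n_trees: int = 300
    nodesize_grid: tuple[int, ...] = (10,)
    nsplit_grid: tuple[int | None, ...] = (2,)
    mtry_grid: tuple[int, ...] = (3,)
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nodesize_grid or not self.nsplit_grid or not self.mtry_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ImportanceResult:
    """Outcome of a forest grid search: the winner and its importances."""

    forest: RandomForestImportance
    vimp: pd.Series
    minimal_depth: pd.Series
    minimal_depth_threshold: float
    oob_error: float
    test_error: float
    chosen: dict
    grid: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Flat per-factor table: vimp, minimal depth, selected flag."""
        df = pd.DataFrame({"vimp": self.vimp, "minimal_depth": self.minimal_depth})
        df["selected"] = df["minimal_depth"] <= self.minimal_depth_threshold
        return df.rename_axis("factor").reset_index()


def fit_forest(
    cohort: CohortTable,
    catalog: FactorCatalog | None = None,
    outcome: str | None = None,
    cfg: ForestConfig | None = None,
    factors: list[str] | None = None,
) -> ImportanceResult:
    """Grid-search the ensemble on an 80/20 split, minimising OOB error.

    Rows with any missing factor value are removed (listwise; missingness
    is *not* recoded here).  Ties in OOB error go to the smaller nodesize,
    then the smaller mtry.  The 20% held-out split gives an additional
    test error for the winning configuration.
    """
    cfg = cfg or ForestConfig()
    catalog = catalog if catalog is not None else cohort.catalog
    if outcome is None:
        outcome = cohort.outcomes[0]
    cols = factors if factors is not None else list(cohort.factor_columns)
    df = cohort.data[cols + [outcome]].dropna()
    y = df[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class after deletion")
    X = df[cols]

    ss = np.random.SeedSequence(cfg.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    forest_seed = int(np.random.default_rng(ss.spawn(2)[1]).integers(2**31))
    perm = split_rng.permutation(len(df))
    n_train = int(round(cfg.train_fraction * len(df)))
    tr, te = perm[:n_train], perm[n_train:]

    rows = []
    fitted: list[RandomForestImportance] = []
    for nodesize in cfg.nodesize_grid:
        for nsplit in cfg.nsplit_grid:
            for mtry in cfg.mtry_grid:
                forest = RandomForestImportance(
                    n_trees=cfg.n_trees,
                    nodesize=nodesize,
                    nsplit=nsplit,
                    mtry=mtry,
                    random_state=forest_seed,
                ).fit(X.iloc[tr], y[tr])
                fitted.append(forest)
                rows.append(
                    {
                        "nodesize": nodesize,
                        "nsplit": nsplit,
                        "mtry": mtry,
                        "oob_error": forest.oob_error_,
                    }
                )
    grid = pd.DataFrame(rows)
    best_idx = int(
        grid.sort_values(["oob_error", "nodesize", "mtry"], kind="stable").index[0]
    )
    best = fitted[best_idx]
    chosen = {
        "nodesize": best.nodesize,
        "nsplit": best.nsplit,
        "mtry": best.mtry,
    }
    test_error = (
        float(np.mean(best.predict(X.iloc[te]) != y[te])) if len(te) else float("nan")
    )
    return ImportanceResult(
        forest=best,
        vimp=best.vimp_,
        minimal_depth=best.minimal_depth_,
        minimal_depth_threshold=best.minimal_depth_threshold_,
        oob_error=best.oob_error_,
        test_error=test_error,
        chosen=chosen,
        grid=grid,
    )
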