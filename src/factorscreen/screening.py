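"""Screening engine: one statistic per (subgroup, outcome), plus views.

:class:`SubgroupScreener` is the workhorse.  It enumerates every 1..D
factorial subgroup of the catalogue and computes the chosen statistic —
the exposure odds ratio against the common control group, or the crude
outcome proportion — for each subgroup and each outcome, in one
vectorised pass per factor (pair).  Empty or single-arm subgroups are kept
and flagged, never dropped, so result tables have a stable shape.

Derived views:

* ``funnel_data`` — (n, display value) pairs around the overall reference,
  the classic funnel whose small-n flare is where striking subgroups hide;
* ``compare_outcomes`` — the same subgroups under two outcomes, for
  bubble-plot style comparison;
* ``interaction_trend`` — a factor's level-wise estimates in ordinal
  order, with a strict-monotonicity verdict ("no data" excluded).

Deliberately absent: per-subgroup p-values or multiplicity adjustment.
The screen is a hypothesis-generating overview; what counts as "striking"
stays a human judgement supported by the views above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .catalog import CohortTable, FactorCatalog, NODATA_LEVEL
from .effect_stats import TruncationConfig
from .enumeration import SubgroupSet, enumerate_subgroups

RESULT_COLUMNS = [
    "subgroup",
    "depth",
    "outcome",
    "n",
    "a",
    "b",
    "c",
    "d",
    "point",
    "ci_low",
    "ci_high",
    "display_point",
    "flags",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one screening run."""

    depth: int = 2
    statistic: str = "odds_ratio"  # or "proportion"
    outcomes: tuple[str, ...] | None = None
    truncation: TruncationConfig = field(default_factory=TruncationConfig)
    min_report_n: int = 0
    ci_level: float = 0.95
    seed: int | None = None


@dataclass(frozen=True)
class TrendReport:
    """Level-wise estimates of one ordered factor for one outcome."""

    factor: str
    outcome: str
    levels: tuple[str, ...]
    estimates: tuple[float, ...]
    monotone_direction: str  # "increasing" | "decreasing" | "none"


def _monotone_direction(values: Sequence[float]) -> str:
    vals = [float(v) for v in values]
    if len(vals) < 2 or any(not math.isfinite(v) for v in vals):
        return "none"
    diffs = np.diff(vals)
    if np.all(diffs < 0):
        return "decreasing"
    if np.all(diffs > 0):
        return "increasing"
    return "none"


class SubgroupScreener(BaseEstimator):
    """Exhaustive subgroup screen as a scikit-learn style estimator.

    Parameters
    ----------
    depth : int, default 2
        Maximum number of combined factor levels per subgroup.  Depth 2 is
        the interpretability sweet spot; deeper subgroups overlap heavily
        and get very small.
    statistic : {"odds_ratio", "proportion"}
        ``odds_ratio``: exposure OR (index vs. reference arm) for cases of
        the outcome against the common control group.  ``proportion``:
        crude case fraction in the subgroup, exposure ignored.
    outcomes : sequence of str or None
        Outcomes to screen; None means all outcomes of the cohort.
    trunc_low, trunc_high : float
        Display truncation bounds for odds ratios (raw values kept).
    min_report_n : int
        Subgroups below this size are *flagged*, never dropped — small
        extreme subgroups should remain discoverable.
    ci_level : float
        Coverage of the per-subgroup Wald interval columns.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (subgroup, outcome): counts a, b, c, d, n, the raw
        point, Wald CI, truncated display value and flags.
    overall_ : pandas.DataFrame
        One row per outcome: the whole-cohort estimate (funnel reference).
    subgroups_ : SubgroupSet
        The enumerated subgroups, in the deterministic canonical order.
    """

    def __init__(
        self,
        depth: int = 2,
        statistic: str = "odds_ratio",
        outcomes: Sequence[str] | None = None,
        trunc_low: float = 0.3,
        trunc_high: float = 15.0,
        min_report_n: int = 0,
        ci_level: float = 0.95,
    ):
        self.depth = depth
        self.statistic = statistic
        self.outcomes = outcomes
        self.trunc_low = trunc_low
        self.trunc_high = trunc_high
        self.min_report_n = min_report_n
        self.ci_level = ci_level

    # ------------------------------------------------------------------

    def fit(self, cohort: CohortTable, catalog: FactorCatalog | None = None):
        """Run the screen over every subgroup x outcome of the cohort."""
        if self.statistic not in ("odds_ratio", "proportion"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        catalog = catalog if catalog is not None else cohort.catalog
        outcomes = tuple(self.outcomes) if self.outcomes else tuple(cohort.outcomes)
        if not outcomes:
            raise ValueError("no outcomes to screen")
        for oc in outcomes:
            if oc not in cohort.outcomes:
                raise KeyError(f"unknown outcome {oc!r}")

        self.catalog_ = catalog
        self.outcomes_ = outcomes
        self.subgroups_ = enumerate_subgroups(catalog, self.depth)

        # integer level codes per factor, -1 = missing
        sorted_factors = sorted(catalog.factors, key=lambda f: f.name)
        codes: dict[str, np.ndarray] = {}
        for fac in sorted_factors:
            cat = pd.Categorical(
                cohort.data[fac.name], categories=list(fac.levels)
            )
            codes[fac.name] = cat.codes.astype(np.int64)

        index = cohort.exposure_index_mask()
        control = cohort.control_mask()

        frames = []
        overall_rows = []
        for oc in outcomes:
            case = cohort.case_mask(oc)
            wa = (case & index).astype(np.float64)
            wb = (case & ~index).astype(np.float64)
            wc = (control & index).astype(np.float64)
            wd = (control & ~index).astype(np.float64)
            cells = self._accumulate_cells(sorted_factors, codes, (wa, wb, wc, wd))
            df = self._finalise(cells, oc)
            frames.append(df)
            overall_rows.append(
                self._overall_row(
                    oc,
                    a=float(wa.sum()),
                    b=float(wb.sum()),
                    c=float(wc.sum()),
                    d=float(wd.sum()),
                )
            )

        keys = [sg.key for sg in self.subgroups_]
        depths = [sg.depth for sg in self.subgroups_]
        for df in frames:
            df.insert(0, "subgroup", keys)
            df.insert(1, "depth", depths)
        self.results_ = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
        self.overall_ = pd.DataFrame(overall_rows).set_index("outcome")
        return self

    # -- internals ------------------------------------------------------

    def _accumulate_cells(self, sorted_factors, codes, weights):
        """2x2 cell counts for every subgroup, in enumeration order.

        For each factor combination the level codes are packed into one
        mixed-radix integer and tallied with ``bincount`` — one vectorised
        pass per combination instead of one per subgroup.
        """
        import itertools

        parts: dict[int, list[np.ndarray]] = {i: [] for i in range(4)}
        for d in range(1, self.depth + 1):
            for combo in itertools.combinations(sorted_factors, d):
                valid = np.ones(len(codes[combo[0].name]), dtype=bool)
                packed = np.zeros(len(valid), dtype=np.int64)
                size = 1
                for fac in combo:
                    c = codes[fac.name]
                    valid &= c >= 0
                    packed = packed * fac.n_levels + np.maximum(c, 0)
                    size *= fac.n_levels
                sel = packed[valid]
                for i, w in enumerate(weights):
                    parts[i].append(
                        np.bincount(sel, weights=w[valid], minlength=size)
                    )
        return [np.concatenate(parts[i]) for i in range(4)]

    def _finalise(self, cells, outcome: str) -> pd.DataFrame:
        a, b, c, d = (x.astype(np.float64) for x in cells)
        n = a + b + c + d
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.statistic == "odds_ratio":
                num = a * d
                den = b * c
                safe_den = np.where(den > 0, den, 1.0)
                point = np.where(den > 0, num / safe_den, np.nan)
                point = np.where((den == 0) & (num > 0), np.inf, point)
                all_pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
                z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
                one = np.maximum  # avoid 1/0 warnings outside all_pos
                se = np.where(
                    all_pos,
                    np.sqrt(1 / one(a, 1) + 1 / one(b, 1) + 1 / one(c, 1) + 1 / one(d, 1)),
                    np.nan,
                )
                log_or = np.where(all_pos, np.log(np.where(all_pos, num / safe_den, 1.0)), np.nan)
                ci_low = np.exp(log_or - z * se)
                ci_high = np.exp(log_or + z * se)
                disp = np.clip(point, self.trunc_low, self.trunc_high)
                disp = np.where(np.isnan(point), self.trunc_low, disp)
            else:  # proportion
                cases = a + b
                point = np.where(n > 0, cases / np.where(n > 0, n, 1.0), np.nan)
                ci_low = np.full_like(point, np.nan)
                ci_high = np.full_like(point, np.nan)
                disp = point

        flags = self._flags(a, b, c, d, n, point, disp)
        return pd.DataFrame(
            {
                "outcome": outcome,
                "n": n.astype(np.int64),
                "a": a.astype(np.int64),
                "b": b.astype(np.int64),
                "c": c.astype(np.int64),
                "d": d.astype(np.int64),
                "point": point,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "display_point": disp,
                "flags": flags,
            }
        )

    def _flags(self, a, b, c, d, n, point, disp) -> list[str]:
        empty = n == 0
        zero_cell = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & ~empty
        single_arm = ((a + c) == 0) | ((b + d) == 0)
        infinite = np.isinf(point)
        undefined = np.isnan(point)
        truncated = (disp != point) & ~np.isnan(point)
        truncated |= undefined & (self.statistic == "odds_ratio")
        below = n < self.min_report_n
        out = []
        for i in range(len(n)):
            f = []
            if empty[i]:
                f.append("empty")
            if self.statistic == "odds_ratio":
                if zero_cell[i]:
                    f.append("zero_cell")
                if single_arm[i] and not empty[i]:
                    f.append("single_arm")
                if infinite[i]:
                    f.append("infinite")
                if undefined[i]:
                    f.append("undefined")
                if truncated[i]:
                    f.append("truncated")
            elif undefined[i]:
                f.append("undefined")
            if below[i]:
                f.append("below_threshold")
            out.append(";".join(f))
        return out

    def _overall_row(self, outcome: str, a: float, b: float, c: float, d: float) -> dict:
        n = a + b + c + d
        if self.statistic == "odds_ratio":
            point = (a * d) / (b * c) if b * c > 0 else (math.inf if a * d > 0 else math.nan)
            if min(a, b, c, d) > 0:
                z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
                se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
                lo, hi = math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)
            else:
                lo = hi = math.nan
        else:
            point = (a + b) / n if n > 0 else math.nan
            lo = hi = math.nan
        return {
            "outcome": outcome,
            "n": int(n),
            "a": int(a),
            "b": int(b),
            "c": int(c),
            "d": int(d),
            "point": point,
            "ci_low": lo,
            "ci_high": hi,
        }

    # -- derived views ---------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "results_"):
            raise RuntimeError("screener is not fitted; call fit() first")

    def funnel_data(self, outcome: str) -> tuple[pd.DataFrame, float]:
        """Funnel-plot table: (subgroup, depth, n, display_point) plus the
        overall reference value of the outcome."""
        self._check_fitted()
        if outcome not in self.outcomes_:
            raise KeyError(f"outcome {outcome!r} was not screened")
        df = self.results_[self.results_["outcome"] == outcome]
        df = df[df["n"] > 0][["subgroup", "depth", "n", "display_point", "flags"]]
        return df.reset_index(drop=True), float(self.overall_.loc[outcome, "point"])

    def compare_outcomes(
        self, outcome_x: str, outcome_y: str
    ) -> tuple[pd.DataFrame, dict[str, float]]:
        """Pair every subgroup's estimates under two outcomes."""
        self._check_fitted()
        for oc in (outcome_x, outcome_y):
            if oc not in self.outcomes_:
                raise KeyError(f"outcome {oc!r} was not screened")
        cols = ["subgroup", "depth", "n", "point", "display_point", "flags"]
        x = self.results_[self.results_["outcome"] == outcome_x][cols]
        y = self.results_[self.results_["outcome"] == outcome_y][cols]
        merged = x.merge(y, on=["subgroup", "depth"], suffixes=("_x", "_y"))
        merged["incomplete"] = (
            merged["point_x"].isna() | merged["point_y"].isna()
        )
        refs = {
            outcome_x: float(self.overall_.loc[outcome_x, "point"]),
            outcome_y: float(self.overall_.loc[outcome_y, "point"]),
        }
        return merged, refs

    def interaction_trend(self, factor: str, outcome: str) -> TrendReport:
        """Level-wise estimates of an *ordered* factor, with a strict
        monotonicity verdict; the "no data" level never enters the trend."""
        self._check_fitted()
        fac = self.catalog_[factor]
        if not fac.is_ordered:
            raise ValueError(f"factor {factor!r} is not ordered; no trend defined")
        levels = fac.trend_levels()
        df = self.results_[
            (self.results_["outcome"] == outcome) & (self.results_["depth"] == 1)
        ].set_index("subgroup")
        ests = []
        for lv in levels:
            key = f"{factor}={lv}"
            ests.append(float(df.loc[key, "point"]) if key in df.index else math.nan)
        return TrendReport(
            factor=factor,
            outcome=outcome,
            levels=levels,
            estimates=tuple(ests),
            monotone_direction=_monotone_direction(ests),
        )

    def top_subgroups(self, outcome: str, k: int = 20) -> pd.DataFrame:
        """Rank subgroups by |log display value| relative to the overall
        reference — a convenience ordering, not a "striking" label."""
        self._check_fitted()
        df, ref = self.funnel_data(outcome)
        df = df[df["n"] >= self.min_report_n].copy()
        if self.statistic == "odds_ratio":
            df["deviation"] = np.abs(np.log(df["display_point"]) - np.log(ref))
        else:
            df["deviation"] = np.abs(df["display_point"] - ref)
        return df.sort_values("deviation", ascending=False).head(k).reset_index(drop=True)


def run_screen(
    cohort: CohortTable,
    catalog: FactorCatalog | None = None,
    cfg: ScreenConfig | None = None,
) -> SubgroupScreener:
    """Functional wrapper: configure, fit and return a :class:`SubgroupScreener`."""
    cfg = cfg or ScreenConfig()
    screener = SubgroupScreener(
        depth=cfg.depth,
        statistic=cfg.statistic,
        outcomes=cfg.outcomes,
        trunc_low=cfg.truncation.trunc_low,
        trunc_high=cfg.truncation.trunc_high,
        min_report_n=cfg.min_report_n,
        ci_level=cfg.ci_level,
    )
    return screener.fit(cohort, catalog)
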