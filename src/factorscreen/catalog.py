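"""Cohort and factor-catalogue data model, file IO, exclusions and recoding.

A *factor* is a categorical subject attribute (e.g. an age group); the
*catalogue* is the registry of all factors and their declared levels and is
the sole source of subgroup enumeration.  A *cohort* is one row per subject
with a binary exposure (index vs. reference arm), one or more binary
outcomes coded ``yes``/``no``, and one column per catalogued factor.

Missing factor values can be made explicit as the reserved level
``"no data"`` so that systematic missingness stays visible during
screening instead of silently shrinking subgroups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Reserved level label absorbing missing factor values.
NODATA_LEVEL = "no data"

#: Tokens treated as missing when reading CSV files (besides true NaN).
DEFAULT_MISSING_TOKENS = ("", "NA")


class ValidationError(ValueError):
    """Raised when an input file violates the declared data model."""


# ---------------------------------------------------------------------------
# Factor / catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Factor:
    """One categorical factor: a name, its ordered list of levels, and flags.

    Parameters
    ----------
    name : str
        Unique identifier, also the cohort column name.
    levels : tuple of str
        Declared level labels, in declared (for ordered factors: ordinal)
        order.  Labels must be unique; the reserved label ``"no data"`` may
        appear at most once and is always excluded from trend sequences.
    is_ordered : bool
        Whether the declared level order is an ordinal scale; interaction
        trend analysis applies only to ordered factors.
    """

    name: str
    levels: tuple[str, ...]
    is_ordered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 1:
            raise ValidationError(f"factor {self.name!r} declares no levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"factor {self.name!r} has duplicate levels")

    @property
    def has_nodata_level(self) -> bool:
        return NODATA_LEVEL in self.levels

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def trend_levels(self) -> tuple[str, ...]:
        """Levels in declared order with the ``"no data"`` level removed."""
        return tuple(lv for lv in self.levels if lv != NODATA_LEVEL)

    def with_nodata_level(self) -> "Factor":
        """Return a copy whose level list includes ``"no data"`` (appended once)."""
        if self.has_nodata_level:
            return self
        return replace(self, levels=self.levels + (NODATA_LEVEL,))


@dataclass(frozen=True)
class FactorCatalog:
    """Registry of factors; the source of all subgroup enumeration."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError("factor names must be unique in a catalogue")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(f.n_levels for f in self.factors)

    @property
    def total_level_count(self) -> int:
        """Sum of per-factor level counts (the catalogue's "221" figure)."""
        return sum(self.level_counts)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            f.name: {"levels": list(f.levels), "ordered": f.is_ordered}
            for f in self.factors
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FactorCatalog":
        factors = []
        for name, spec in d.items():
            if isinstance(spec, Mapping):
                factors.append(
                    Factor(
                        name=str(name),
                        levels=tuple(str(x) for x in spec["levels"]),
                        is_ordered=bool(spec.get("ordered", False)),
                    )
                )
            else:  # bare list of levels
                factors.append(Factor(name=str(name), levels=tuple(str(x) for x in spec)))
        return cls(tuple(factors))

    @classmethod
    def from_file(cls, path: str | Path) -> "FactorCatalog":
        """Read a catalogue from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """One row per subject: id, binary exposure, binary outcomes, factor values.

    ``data`` holds the columns; ``index_label``/``reference_label`` fix the
    exposure orientation explicitly (odds ratios > 1 mean higher odds in the
    *index* arm).  Factor columns are object-dtype level labels with ``NaN``
    for missing.
    """

    data: pd.DataFrame
    catalog: FactorCatalog
    exposure: str = "exposure"
    outcomes: tuple[str, ...] = ()
    subject_id: str = "subject_id"
    index_label: str = "low"
    reference_label: str = "high"

    def __post_init__(self) -> None:
        self.outcomes = tuple(self.outcomes)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def factor_columns(self) -> tuple[str, ...]:
        return tuple(n for n in self.catalog.factor_names if n in self.data.columns)

    def subject_ids(self) -> pd.Series:
        return self.data[self.subject_id]

    def exposure_index_mask(self) -> np.ndarray:
        """Boolean array: subject is in the index (e.g. low-SES) arm."""
        return (self.data[self.exposure] == self.index_label).to_numpy()

    def case_mask(self, outcome: str) -> np.ndarray:
        """Boolean array: subject is a case of ``outcome``."""
        if outcome not in self.outcomes:
            raise KeyError(f"unknown outcome {outcome!r}")
        return (self.data[outcome] == "yes").to_numpy()

    def control_mask(self) -> np.ndarray:
        """Common control group: subjects with *no* outcome present."""
        m = np.ones(self.n, dtype=bool)
        for oc in self.outcomes:
            m &= (self.data[oc] == "no").to_numpy()
        return m

    def factor_missing_mask(self, factor: str) -> np.ndarray:
        return self.data[factor].isna().to_numpy()

    # -- validation ---------------------------------------------------------

    def validate(self, allow_missing_exposure: bool = False) -> None:
        df = self.data
        if df[self.subject_id].duplicated().any():
            dup = df[self.subject_id][df[self.subject_id].duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        if not allow_missing_exposure:
            valid_exp = {self.index_label, self.reference_label}
            bad = ~df[self.exposure].isin(valid_exp)
            if bad.any():
                raise ValidationError(
                    f"exposure column {self.exposure!r} has values outside "
                    f"{sorted(valid_exp)} in {int(bad.sum())} rows "
                    "(apply exclusions first)"
                )
            for oc in self.outcomes:
                bad = ~df[oc].isin(["yes", "no"])
                if bad.any():
                    raise ValidationError(
                        f"outcome {oc!r} has non-yes/no values in {int(bad.sum())} rows"
                    )
        for name in self.factor_columns:
            levels = set(self.catalog[name].levels)
            col = df[name]
            bad = col.notna() & ~col.isin(levels)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {i}: value {col.iloc[i]!r} is not a declared level "
                    f"of factor {name!r}"
                )

    # -- IO -----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort as UTF-8 comma-separated text, missing as empty."""
        self.data.to_csv(path, index=False, encoding="utf-8")

    def copy(self, data: pd.DataFrame | None = None) -> "CohortTable":
        return CohortTable(
            data=self.data.copy() if data is None else data,
            catalog=self.catalog,
            exposure=self.exposure,
            outcomes=self.outcomes,
            subject_id=self.subject_id,
            index_label=self.index_label,
            reference_label=self.reference_label,
        )


def read_cohort(
    path: str | Path,
    catalog: FactorCatalog,
    column_map: Mapping[str, str] | None = None,
    *,
    exposure: str = "exposure",
    outcomes: Sequence[str] = (),
    subject_id: str = "subject_id",
    index_label: str = "low",
    reference_label: str = "high",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    validate: bool = True,
) -> CohortTable:
    """Read a cohort CSV and validate it against the catalogue.

    ``column_map`` maps raw file column names to canonical names (subject id,
    exposure, outcomes, factor names); unmapped extra columns are dropped with
    a logged warning.  Rows keep file order.  Empty strings and the tokens in
    ``missing_tokens`` read as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_tokens),
        encoding="utf-8",
    )
    if column_map:
        missing_cols = [c for c in column_map if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"mapped columns absent from file: {missing_cols}")
        df = df.rename(columns=dict(column_map))
    expected = {subject_id, exposure, *outcomes, *catalog.factor_names}
    extra = [c for c in df.columns if c not in expected]
    for c in extra:
        logger.warning("ignoring unmapped column %r", c)
    df = df[[c for c in df.columns if c in expected]]
    absent = expected - set(df.columns)
    # factors may legitimately be absent from a file; id/exposure/outcomes may not
    required_absent = absent - set(catalog.factor_names)
    if required_absent:
        raise ValidationError(f"required columns missing: {sorted(required_absent)}")
    cohort = CohortTable(
        data=df.reset_index(drop=True),
        catalog=catalog,
        exposure=exposure,
        outcomes=tuple(outcomes),
        subject_id=subject_id,
        index_label=index_label,
        reference_label=reference_label,
    )
    if validate:
        cohort.validate(allow_missing_exposure=True)
        if df[subject_id].duplicated().any():
            raise ValidationError("duplicate subject_id")
    return cohort


# ---------------------------------------------------------------------------
# Exclusions and recoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionConfig:
    """Row-exclusion rules applied before analysis.

    Rules are applied in declared order with first-match attribution, so the
    per-rule tally is deterministic: a row failing several rules is counted
    against the first one only.

    ``drop_exposure_levels`` removes raw exposure labels (e.g. a middle
    exposure category kept out of a low-vs-high contrast).
    ``drop_if_missing`` removes rows missing any of the named columns
    (typically exposure and all outcome columns).  ``drop_filter`` is an
    optional ``(column, predicate)`` pair removing rows where the predicate
    holds (e.g. an age band with unreliable diagnoses).
    """

    drop_exposure_levels: tuple[str, ...] = ()
    drop_if_missing: tuple[str, ...] = ()
    drop_filter: tuple[str, Callable[[pd.Series], pd.Series]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drop_exposure_levels", tuple(self.drop_exposure_levels))
        object.__setattr__(self, "drop_if_missing", tuple(self.drop_if_missing))


def apply_exclusions(
    cohort: CohortTable, cfg: ExclusionConfig
) -> tuple[CohortTable, dict[str, int]]:
    """Apply exclusion rules; return the reduced cohort and a per-rule tally.

    The tally keys are ``exposure_level:<label>``, ``missing:<column>`` and
    ``filter:<column>``; values sum to ``rows_in - rows_out``.
    """
    df = cohort.data
    removed = np.zeros(len(df), dtype=bool)
    tally: dict[str, int] = {}

    for lab in cfg.drop_exposure_levels:
        hit = (df[cohort.exposure] == lab).to_numpy() & ~removed
        tally[f"exposure_level:{lab}"] = int(hit.sum())
        removed |= hit
    for col in cfg.drop_if_missing:
        if col not in df.columns:
            raise ValidationError(f"drop_if_missing column {col!r} not in cohort")
        hit = df[col].isna().to_numpy() & ~removed
        tally[f"missing:{col}"] = int(hit.sum())
        removed |= hit
    if cfg.drop_filter is not None:
        col, pred = cfg.drop_filter
        if col not in df.columns:
            raise ValidationError(f"drop_filter column {col!r} not in cohort")
        hit = pred(df[col]).to_numpy().astype(bool) & ~removed
        tally[f"filter:{col}"] = int(hit.sum())
        removed |= hit

    out = cohort.copy(data=df.loc[~removed].reset_index(drop=True))
    return out, tally


def recode_missing_to_nodata(
    cohort: CohortTable, catalog: FactorCatalog | None = None
) -> tuple[CohortTable, FactorCatalog]:
    """Recode missing factor values to the explicit level ``"no data"``.

    Every factor with at least one missing value gains the ``"no data"``
    level (once); row count is unchanged.  Exposure and outcome missingness
    must already have been excluded.
    """
    catalog = catalog if catalog is not None else cohort.catalog
    df = cohort.data.copy()
    new_factors = []
    for fac in catalog:
        if fac.name in df.columns and df[fac.name].isna().any():
            df[fac.name] = df[fac.name].fillna(NODATA_LEVEL)
            new_factors.append(fac.with_nodata_level())
        else:
            new_factors.append(fac)
    new_catalog = FactorCatalog(tuple(new_factors))
    out = cohort.copy(data=df)
    out.catalog = new_catalog
    return out, new_catalog


def bin_numeric_column(
    values: Iterable[float],
    cut_points: Sequence[float],
    labels: Sequence[str],
) -> list[str | None]:
    """Bin numeric values into right-closed classes.

    ``labels[i]`` covers ``cut_points[i-1] < v <= cut_points[i]`` with the
    extreme intervals open-ended; a value exactly at a cut point goes to the
    lower bin.  Missing values (None/NaN) stay missing.
    """
    cuts = np.asarray(cut_points, dtype=float)
    if len(labels) != len(cuts) + 1:
        raise ValueError("need exactly len(cut_points)+1 labels")
    if len(cuts) and np.any(np.diff(cuts) <= 0):
        raise ValueError("cut_points must be strictly ascending")
    out: list[str | None] = []
    for i, v in enumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(None)
            continue
        try:
            x = float(v)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric value at index {i}: {v!r}") from None
        idx = int(np.searchsorted(cuts, x, side="left"))
        out.append(str(labels[idx]))
    return out
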