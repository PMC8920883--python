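"""Shared fixtures: tiny catalogues and cohorts built in memory."""

import numpy as np
import pandas as pd
import pytest

from factorscreen import CohortTable, Factor, FactorCatalog


@pytest.fixture
def sex_age_catalog() -> FactorCatalog:
    """The canonical worked example: 2 sex levels x 4 age groups."""
    return FactorCatalog(
        (
            Factor("age", ("4-6", "7-10", "11-13", "14-17"), is_ordered=True),
            Factor("sex", ("boy", "girl")),
        )
    )


@pytest.fixture
def small_cohort(sex_age_catalog) -> CohortTable:
    """Deterministic 40-subject cohort over sex x age with two outcomes."""
    rng = np.random.default_rng(7)
    n = 40
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "exposure": rng.choice(["low", "high"], size=n, p=[0.4, 0.6]),
            "asthma": rng.choice(["yes", "no"], size=n, p=[0.2, 0.8]),
            "rhinitis": "no",
            "age": rng.choice(["4-6", "7-10", "11-13", "14-17"], size=n),
            "sex": rng.choice(["boy", "girl"], size=n),
        }
    )
    # keep outcomes mutually exclusive: rhinitis yes only where asthma no
    flip = (df["asthma"] == "no") & (rng.random(n) < 0.25)
    df.loc[flip, "rhinitis"] = "yes"
    return CohortTable(
        data=df,
        catalog=sex_age_catalog,
        outcomes=("asthma", "rhinitis"),
    )


def make_cohort_csv(tmp_path, rows: list[dict], name: str = "cohort.csv"):
    """Write a list of row dicts as a cohort CSV; returns the path."""
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
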