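"""Exhaustive enumeration of 1..D-factorial subgroups.

A subgroup is the set of subjects satisfying a conjunction of
``factor=level`` constraints, at most one constraint per factor.  With a
depth cap of 2 (the default), a catalogue with per-factor level counts
``l_1..l_p`` yields ``sum(l_i) + sum_{i<j} l_i*l_j`` subgroups — e.g. a
2-level and a 4-level factor give 6 singles plus 8 pairs, 14 in all.

Empty subgroups (level combinations with no subjects) are enumerated like
any other: emptiness is a property of membership in a particular cohort,
not of the catalogue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .catalog import CohortTable, FactorCatalog


@dataclass(frozen=True)
class Subgroup:
    """A conjunction of ``(factor, level)`` constraints.

    Constraints are stored canonically ordered (factor name, then level) so
    that equal subgroups compare and hash equal regardless of construction
    order.
    """

    constraints: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        canon = tuple(sorted(tuple(c) for c in self.constraints))
        if len({f for f, _ in canon}) != len(canon):
            raise ValueError("a factor may not be constrained twice in one subgroup")
        if not canon:
            raise ValueError("a subgroup needs at least one constraint")
        object.__setattr__(self, "constraints", canon)

    @property
    def depth(self) -> int:
        return len(self.constraints)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.constraints)

    @property
    def key(self) -> str:
        """Stable text key, e.g. ``"age=11-13 + sex=girl"``."""
        return " + ".join(f"{f}={lv}" for f, lv in self.constraints)

    def to_dict(self) -> dict[str, str]:
        return dict(self.constraints)

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Subgroup":
        return cls(tuple(d.items()))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


@dataclass(frozen=True)
class SubgroupSet:
    """All subgroups enumerated from a catalogue up to a depth cap."""

    subgroups: tuple[Subgroup, ...]
    depth_cap: int

    def __iter__(self) -> Iterator[Subgroup]:
        return iter(self.subgroups)

    def __len__(self) -> int:
        return len(self.subgroups)

    def __getitem__(self, i: int) -> Subgroup:
        return self.subgroups[i]


def enumerate_subgroups(catalog: FactorCatalog, depth_cap: int = 2) -> SubgroupSet:
    """Enumerate every subgroup of depth 1..``depth_cap``.

    Order is deterministic: ascending depth; factors lexicographic by name;
    levels in declared order — byte-identical across runs on the same
    catalogue.
    """
    if depth_cap < 1:
        raise ValueError("depth_cap must be >= 1")
    factors = sorted(catalog.factors, key=lambda f: f.name)
    out: list[Subgroup] = []
    for d in range(1, depth_cap + 1):
        for combo in itertools.combinations(factors, d):
            for levels in itertools.product(*(f.levels for f in combo)):
                out.append(
                    Subgroup(tuple((f.name, lv) for f, lv in zip(combo, levels)))
                )
    return SubgroupSet(tuple(out), depth_cap)


def count_subgroups(level_counts: Sequence[int], depth_cap: int = 2) -> int:
    """Closed-form count of 1..D-factorial subgroups.

    For D=2 this is ``sum(l) + (sum(l)^2 - sum(l^2)) / 2``; general D sums
    the elementary symmetric polynomials e_1..e_D of the level counts,
    computed by polynomial expansion of the product ``prod(1 + l_i x)``.
    """
    counts = [int(c) for c in level_counts]
    if any(c < 1 for c in counts):
        raise ValueError("level counts must be >= 1")
    if depth_cap < 1:
        raise ValueError("depth_cap must be >= 1")
    d = min(depth_cap, len(counts))
    # e[k] accumulates the elementary symmetric polynomial of order k
    e = [1] + [0] * d
    for c in counts:
        for k in range(d, 0, -1):
            e[k] += e[k - 1] * c
    return sum(e[1:])


def member_mask(subgroup: Subgroup, cohort: CohortTable) -> np.ndarray:
    """Boolean row mask of the subgroup's members in the cohort.

    Rows with a missing value for a constrained factor match no level and
    are excluded.
    """
    mask = np.ones(cohort.n, dtype=bool)
    for factor, level in subgroup.constraints:
        if factor not in cohort.data.columns:
            raise KeyError(f"factor {factor!r} not in cohort")
        if level not in cohort.catalog[factor].levels:
            raise KeyError(f"{level!r} is not a declared level of {factor!r}")
        mask &= (cohort.data[factor] == level).to_numpy()
    return mask


def members(subgroup: Subgroup, cohort: CohortTable) -> frozenset:
    """Subject ids of all members of the subgroup (conjunction of constraints)."""
    m = member_mask(subgroup, cohort)
    return frozenset(cohort.subject_ids()[m])


def complement(subgroup: Subgroup, cohort: CohortTable) -> frozenset:
    """Subject ids of the complementary group: the cohort minus the subgroup."""
    m = member_mask(subgroup, cohort)
    return frozenset(cohort.subject_ids()[~m])


def factorial_context(subgroup: Subgroup, catalog: FactorCatalog) -> list[Subgroup]:
    """All subgroups over the same factor set: the subgroup's "siblings".

    One subgroup per level combination of the constrained factors, the
    selected subgroup included.  For a depth-1 subgroup on a k-level factor
    this returns k subgroups.
    """
    facs = [catalog[f] for f in subgroup.factors]
    return [
        Subgroup(tuple((f.name, lv) for f, lv in zip(facs, levels)))
        for levels in itertools.product(*(f.levels for f in facs))
    ]
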