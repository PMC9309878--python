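"""Core-terminal-ancestor nomination, derived families and sharing partitions.

A *candidate* terminal ancestor of a population is one reached through
three or more breeding (crossing) cycles by at least one population member.
Candidates with at least two of the four prominence indicators — nuclear
contribution, cytoplasmic contribution, number of derived cultivars and
breeding-cycle count — strictly above the candidate mean are nominated as
*core* terminal ancestors.  A core ancestor together with all population
members derived from it forms an ancestor-derived family.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contribution import population_contribution
from .pedigree import PedigreeGraph

__all__ = [
    "FamilyRecord",
    "candidate_ancestors",
    "nominate_core_ancestors",
    "ancestor_family",
    "family_table",
    "rank_major_ancestors",
    "sharing_partition",
    "core_ancestor_share",
    "family_nuclear_share",
]

INDICATORS = ("ngc_percent", "cgc_percent", "n_derived", "max_cycles")

DEFAULT_MIN_CYCLES = 3
DEFAULT_MIN_INDICATORS = 2


@dataclass(frozen=True)
class FamilyRecord:
    """An ancestor-derived family within a fixed population."""

    ancestor: str
    members: frozenset[str]
    ngc_percent: float
    cgc_percent: float
    region_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def candidate_ancestors(
    graph: PedigreeGraph,
    population: Sequence[str],
    min_cycles: int = DEFAULT_MIN_CYCLES,
) -> pd.DataFrame:
    """Indicator table of candidate terminal ancestors of ``population``.

    Rows: every terminal ancestor of any population member whose maximum
    breeding-cycle count over its derived members is >= ``min_cycles``.
    Columns: the four prominence indicators plus the ancestor's origin
    ecoregion, indexed by ancestor id.
    """
    population = list(population)
    if not population:
        raise ValueError("population must be nonempty")
    terminals = sorted(set().union(*(graph.terminal_ancestors(c) for c in population)))
    rows = []
    for anc in terminals:
        pc = population_contribution(graph, population, anc)
        if pc.max_cycles >= min_cycles:
            rows.append(
                (
                    anc,
                    pc.ngc_percent,
                    pc.cgc_percent,
                    pc.n_derived,
                    pc.max_cycles,
                    graph.record(anc).ecoregion.value,
                )
            )
    return pd.DataFrame(
        rows, columns=("ancestor",) + INDICATORS + ("origin",)
    ).set_index("ancestor")


def nominate_core_ancestors(
    table: pd.DataFrame,
    min_indicators: int = DEFAULT_MIN_INDICATORS,
    within_origin: bool = True,
) -> frozenset[str]:
    """Candidates with >= ``min_indicators`` indicators strictly above the mean.

    With ``within_origin=True`` (default) each candidate is compared against
    the mean of candidates sharing its origin ecoregion; otherwise against
    the pooled candidate mean.  Ties at the mean do not count.
    """
    if table.empty:
        return frozenset()
    groups = (
        table.groupby("origin", group_keys=False)
        if within_origin and "origin" in table.columns
        else [(None, table)]
    )
    core: set[str] = set()
    for _, sub in groups:
        means = sub[list(INDICATORS)].mean()
        above = (sub[list(INDICATORS)] > means).sum(axis=1)
        core |= set(sub.index[above >= min_indicators])
    return frozenset(core)


def ancestor_family(
    graph: PedigreeGraph, ancestor: str, population: Sequence[str]
) -> FamilyRecord:
    """The ancestor-derived family of ``ancestor`` within ``population``."""
    if not graph.is_terminal(ancestor):
        raise ValueError(f"{ancestor!r} is not a terminal ancestor")
    population = list(population)
    members = graph.derived_cultivars(ancestor, population)
    pc = population_contribution(graph, population, ancestor)
    counts = Counter(graph.record(m).ecoregion.value for m in members)
    return FamilyRecord(
        ancestor=ancestor,
        members=members,
        ngc_percent=pc.ngc_percent,
        cgc_percent=pc.cgc_percent,
        region_counts=dict(counts),
    )


def family_table(
    graph: PedigreeGraph, ancestors: Sequence[str], population: Sequence[str]
) -> pd.DataFrame:
    """Per-family report over several ancestors (one row per family).

    ``member_times`` counts (cultivar, family) incidences, so its total over
    rows can exceed the number of distinct derived cultivars when families
    overlap.
    """
    rows = []
    regions = sorted(
        {graph.record(c).ecoregion.value for c in population}
    )
    for anc in ancestors:
        fam = ancestor_family(graph, anc, population)
        rows.append(
            [anc, fam.size, fam.ngc_percent, fam.cgc_percent]
            + [fam.region_counts.get(r, 0) for r in regions]
        )
    return pd.DataFrame(
        rows,
        columns=["ancestor", "member_times", "ngc_percent", "cgc_percent"] + regions,
    ).set_index("ancestor")


def rank_major_ancestors(
    table: pd.DataFrame, core: Iterable[str], k: int
) -> list[str]:
    """Top-``k`` core ancestors ranked on derived count, then NGC, then CGC."""
    sub = table.loc[sorted(set(core) & set(table.index))]
    ranked = sub.sort_values(
        ["n_derived", "ngc_percent", "cgc_percent"], ascending=False, kind="mergesort"
    )
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# sharing partitions (Venn cells) and report-level shares
# ---------------------------------------------------------------------------


def sharing_partition(
    item_sets: Mapping[str, Iterable[str]]
) -> dict[frozenset[str], frozenset[str]]:
    """Exact exclusive partition of region item sets into Venn cells.

    Keys are nonempty region combinations; values the items belonging to
    exactly those regions.  Cells union to the overall item union and are
    pairwise disjoint.  Empty cells are included with empty values.
    """
    regions = sorted(item_sets)
    if len(regions) < 2:
        raise ValueError("at least two regions are required")
    sets = {r: frozenset(item_sets[r]) for r in regions}
    cells: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(regions) + 1):
        for combo in itertools.combinations(regions, r):
            inside = frozenset.intersection(*(sets[c] for c in combo))
            outside = frozenset().union(
                *(sets[c] for c in regions if c not in combo)
            ) if len(combo) < len(regions) else frozenset()
            cells[frozenset(combo)] = inside - outside
    return cells


def core_ancestor_share(core: Iterable[str], terminals: Iterable[str]) -> float:
    """Core ancestors as a percentage of all terminal ancestors."""
    core, terminals = set(core), set(terminals)
    if not terminals:
        raise ValueError("terminal-ancestor set must be nonempty")
    if not core <= terminals:
        raise ValueError("core ancestors must be a subset of the terminal ancestors")
    return 100.0 * len(core) / len(terminals)


def family_nuclear_share(ngc_sums: Iterable[float], population_size: int) -> float:
    """Combined family nuclear contribution, % of the population genome.

    ``ngc_sums`` are per-family summed nuclear contributions over the
    population (cultivar-equivalents); the share is their total divided by
    the population size.
    """
    if population_size <= 0:
        raise ValueError("population size must be positive")
    return 100.0 * sum(ngc_sums) / population_size
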