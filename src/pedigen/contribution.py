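"""Nuclear/cytoplasmic genetic contribution and coefficient of parentage.

Contribution rules for inbred-line breeding programs:

* a cross transmits half of each parent's genome, so a terminal ancestor's
  nuclear contribution to a descendant is the sum of ``(1/2)**n_crosses``
  over all distinct pedigree paths;
* pure-line selection and mutation transmit the full genome (weight 1);
* the cytoplasm follows the maternal line: the female slot of every cross
  and the single source of every selection/mutation, up to one terminal
  ancestor which contributes 1.

The coefficient of parentage (COP) is the probability that two lines carry
the same allele identical by descent, evaluated recursively: COP of a line
with itself is 1, distinct terminal ancestors are unrelated (0), a cross
child averages its parents' COP values, and a selected or mutant line has
COP 0.75 with its antecedent (the 0.75 factor is propagated multiplicatively
along selection edges when recursing further).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import BreedingMethod, PedigreeGraph

__all__ = [
    "ContributionProfile",
    "PopulationContribution",
    "nuclear_contribution",
    "cytoplasmic_ancestor",
    "contribution_profile",
    "cop",
    "cop_matrix",
    "population_contribution",
    "write_square_matrix",
    "read_square_matrix",
    "write_profiles",
]

SELECTION_COP = 0.75  # COP between a selected/mutant line and its antecedent

_SINGLE_SOURCE = (BreedingMethod.SELECTION, BreedingMethod.MUTATION)


@dataclass(frozen=True)
class ContributionProfile:
    """Per-cultivar terminal-ancestor contribution accounting."""

    cultivar: str
    nuclear: Mapping[str, float]  # terminal ancestor -> share of the genome
    cytoplasmic_ancestor: str

    def __post_init__(self) -> None:
        total = sum(self.nuclear.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"nuclear contributions of {self.cultivar!r} sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class PopulationContribution:
    """One terminal ancestor's prominence indicators within a population."""

    ancestor: str
    ngc_percent: float  # mean nuclear contribution to the population, x100
    cgc_percent: float  # share of the population on this maternal line, x100
    n_derived: int
    max_cycles: int


def nuclear_contribution(graph: PedigreeGraph, cultivar: str) -> dict[str, float]:
    """Terminal-ancestor nuclear shares of ``cultivar`` (sum to 1)."""
    memo: dict[str, dict[str, float]] = {}

    def shares(node: str) -> dict[str, float]:
        if node in memo:
            return memo[node]
        rec = graph.record(node)
        if rec.is_terminal:
            out = {node: 1.0}
        elif rec.method is BreedingMethod.CROSS:
            out = {}
            for p in rec.parents:
                for anc, w in shares(p).items():
                    out[anc] = out.get(anc, 0.0) + 0.5 * w
        else:  # selection / mutation: full weight from the single source
            out = dict(shares(rec.parents[0]))
        memo[node] = out
        return out

    return dict(shares(cultivar))


def cytoplasmic_ancestor(graph: PedigreeGraph, cultivar: str) -> str:
    """Terminal ancestor of the maternal (cytoplasm) line of ``cultivar``."""
    node = cultivar
    while not graph.record(node).is_terminal:
        node = graph.record(node).parents[0]  # female slot / single source
    return node


def contribution_profile(graph: PedigreeGraph, cultivar: str) -> ContributionProfile:
    return ContributionProfile(
        cultivar=cultivar,
        nuclear=nuclear_contribution(graph, cultivar),
        cytoplasmic_ancestor=cytoplasmic_ancestor(graph, cultivar),
    )


# ---------------------------------------------------------------------------
# coefficient of parentage
# ---------------------------------------------------------------------------


class _CopEvaluator:
    """Memoized recursive COP evaluation over one pedigree graph."""

    def __init__(self, graph: PedigreeGraph) -> None:
        self.graph = graph
        self.memo: dict[frozenset[str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        ga = self.graph
        ga.record(a)
        ga.record(b)
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key in self.memo:
            return self.memo[key]
        # expand the member that is NOT an ancestor of the other; if neither
        # is, expand either (both directions give the same value, the choice
        # is made deterministic for memo stability)
        if a in ga.ancestors(b):
            val = self._expand(b, a)
        elif b in ga.ancestors(a):
            val = self._expand(a, b)
        else:
            ra, rb = ga.record(a), ga.record(b)
            if ra.is_terminal and rb.is_terminal:
                val = 0.0  # distinct terminal ancestors are unrelated
            elif ra.is_terminal:
                val = self._expand(b, a)
            else:
                val = self._expand(a, b)
        self.memo[key] = val
        return val

    def _expand(self, child: str, other: str) -> float:
        rec = self.graph.record(child)
        if rec.method is BreedingMethod.CROSS:
            f, m = rec.parents
            return 0.5 * (self(f, other) + self(m, other))
        # selection/mutation: anchored at 0.75 with the antecedent and
        # decayed multiplicatively beyond it
        return SELECTION_COP * self(rec.parents[0], other)


def cop(graph: PedigreeGraph, a: str, b: str) -> float:
    """Coefficient of parentage between two cultivars, in [0, 1]."""
    return _CopEvaluator(graph)(a, b)


def cop_matrix(graph: PedigreeGraph, ids: Sequence[str]) -> pd.DataFrame:
    """Symmetric COP matrix over ``ids`` (diagonal 1), as a DataFrame."""
    ids = list(ids)
    ev = _CopEvaluator(graph)
    n = len(ids)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = ev(ids[i], ids[j])
    return pd.DataFrame(vals, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# population-level aggregation
# ---------------------------------------------------------------------------


def population_contribution(
    graph: PedigreeGraph, population: Sequence[str], ancestor: str
) -> PopulationContribution:
    """Aggregate one terminal ancestor's indicators over a population.

    NGC% is the ancestor's summed nuclear contribution divided by the
    population size; CGC% the fraction of the population whose maternal
    line traces to the ancestor; ``max_cycles`` the deepest cross count
    over the derived members.
    """
    population = list(population)
    if not population:
        raise ValueError("population must be nonempty")
    total_ngc = 0.0
    n_cyto = 0
    derived: list[str] = []
    for c in population:
        shares = nuclear_contribution(graph, c)
        if ancestor in shares:
            total_ngc += shares[ancestor]
            derived.append(c)
        if cytoplasmic_ancestor(graph, c) == ancestor:
            n_cyto += 1
    max_cycles = max(
        (graph.breeding_cycles(ancestor, c) for c in derived), default=0
    )
    n = len(population)
    return PopulationContribution(
        ancestor=ancestor,
        ngc_percent=100.0 * total_ngc / n,
        cgc_percent=100.0 * n_cyto / n,
        n_derived=len(derived),
        max_cycles=max_cycles,
    )


# ---------------------------------------------------------------------------
# I/O helpers shared by COP and marker-similarity matrices
# ---------------------------------------------------------------------------


def write_square_matrix(m: pd.DataFrame, path: str | Path, scale: float = 1.0) -> None:
    """Square relationship matrix as TSV with id header row and column."""
    (m * scale).to_csv(path, sep="\t", index_label="id", float_format="%.6f")


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profiles(
    graph: PedigreeGraph, cultivars: Iterable[str], path: str | Path
) -> None:
    """Long-format TSV of contribution profiles."""
    rows = []
    for c in cultivars:
        prof = contribution_profile(graph, c)
        for anc in sorted(prof.nuclear):
            rows.append(
                (c, anc, prof.nuclear[anc], int(anc == prof.cytoplasmic_ancestor))
            )
    df = pd.DataFrame(
        rows, columns=["cultivar", "ancestor", "nuclear_contribution", "is_cytoplasmic"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
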