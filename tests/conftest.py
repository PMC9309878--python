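"""Shared fixtures: the Nannong 32 worked pedigree and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pedigen import (
    BreedingMethod,
    CultivarRecord,
    Ecoregion,
    PedigreeGraph,
    SimConfig,
    simulate_breeding_program,
)

NANNONG = "Nannong 32"

# Terminal ancestors of Nannong 32 with their published nuclear contributions
NANNONG_CONTRIBUTIONS = {
    "73-01-1": 0.25,
    "Huaiyindasili": 0.25,
    "Fengxiansuidaohuang": 0.125,
    "51-83": 0.125,
    "Dangshanwandousha": 0.125,
    "Tongshantianedan": 0.0625,
    "Mamotan": 0.0625,
}
NANNONG_CYTOPLASM = "Fengxiansuidaohuang"


def _cross(cid: str, female: str, male: str, eco=Ecoregion.SC) -> CultivarRecord:
    return CultivarRecord(
        id=cid,
        name=cid,
        method=BreedingMethod.CROSS,
        female_or_source=female,
        male=male,
        ecoregion=eco,
    )


@pytest.fixture(scope="session")
def nannong_graph() -> PedigreeGraph:
    """Pedigree of the cultivar Nannong 32.

    The interior crossing structure reproduces the published terminal-
    ancestor contributions and maternal line; the unnamed intermediate
    breeding lines carry synthetic placeholder ids (NN-mid-*).
    """
    terminals = [
        CultivarRecord(id=t, name=t, ecoregion=Ecoregion.SC)
        for t in NANNONG_CONTRIBUTIONS
    ]
    crosses = [
        _cross("Chuxiu", "73-01-1", "Huaiyindasili"),
        _cross("NN-mid-1", "Tongshantianedan", "Mamotan"),  # synthetic interior line
        _cross("NN-mid-2", "Dangshanwandousha", "NN-mid-1"),  # synthetic interior line
        _cross("NN-mid-3", "Fengxiansuidaohuang", "51-83"),  # synthetic interior line
        _cross("Nannong 87-23", "NN-mid-3", "NN-mid-2"),
        _cross(NANNONG, "Nannong 87-23", "Chuxiu"),
    ]
    return PedigreeGraph(terminals + crosses)


@pytest.fixture(scope="session")
def ladder_graph() -> PedigreeGraph:
    """Four nested crosses: base founders sit at breeding-cycle depth 4."""
    recs = [CultivarRecord(id=f"F{i}", name=f"F{i}") for i in range(5)]
    child = "F0"
    for i in range(1, 5):
        recs.append(_cross(f"L{i}", child, f"F{i}"))
        child = f"L{i}"
    return PedigreeGraph(recs)


def small_sim_graph(seed: int, **overrides) -> PedigreeGraph:
    params = dict(
        n_regions=2,
        founders_per_region=4,
        generations=3,
        crosses_per_generation=6,
        selection_fraction=0.2,
        migration_rate=0.2,
        seed=seed,
    )
    params.update(overrides)
    return simulate_breeding_program(SimConfig(**params))


# ---------------------------------------------------------------------------
# brute-force pedigree oracles (independent of the library implementations)
# ---------------------------------------------------------------------------


def oracle_terminal_ancestors(graph: PedigreeGraph, cultivar: str) -> set[str]:
    rec = graph.record(cultivar)
    if not rec.parents:
        return {cultivar}
    out: set[str] = set()
    for p in rec.parents:
        out |= oracle_terminal_ancestors(graph, p)
    return out


def oracle_path_contributions(graph: PedigreeGraph, cultivar: str) -> dict[str, float]:
    """Sum of (1/2)^(#crosses) over all distinct root-ward paths."""
    out: dict[str, float] = {}

    def walk(node: str, weight: float) -> None:
        rec = graph.record(node)
        if not rec.parents:
            out[node] = out.get(node, 0.0) + weight
            return
        if rec.method is BreedingMethod.CROSS:
            for p in rec.parents:
                walk(p, weight * 0.5)
        else:
            walk(rec.parents[0], weight)

    walk(cultivar, 1.0)
    return out


def oracle_max_crosses(graph: PedigreeGraph, ancestor: str, cultivar: str) -> int:
    """Longest cross-count over all pedigree paths, by full enumeration."""
    best = -1

    def walk(node: str, crosses: int) -> None:
        nonlocal best
        if node == ancestor:
            best = max(best, crosses)
            return
        rec = graph.record(node)
        step = 1 if rec.method is BreedingMethod.CROSS else 0
        for p in rec.parents:
            walk(p, crosses + step)

    walk(cultivar, 0)
    return best


def oracle_cop(graph: PedigreeGraph, a: str, b: str) -> float:
    """Unmemoized literal transcription of the parentage rules."""
    if a == b:
        return 1.0
    ra, rb = graph.record(a), graph.record(b)
    a_anc_of_b = a in graph.ancestors(b)
    b_anc_of_a = b in graph.ancestors(a)
    if ra.is_terminal and rb.is_terminal:
        return 0.0

    def expand(child: str, other: str) -> float:
        rec = graph.record(child)
        if rec.method is BreedingMethod.CROSS:
            f, m = rec.parents
            return 0.5 * (oracle_cop(graph, f, other) + oracle_cop(graph, m, other))
        return 0.75 * oracle_cop(graph, rec.parents[0], other)

    if a_anc_of_b:
        return expand(b, a)
    if b_anc_of_a:
        return expand(a, b)
    if ra.is_terminal:
        return expand(b, a)
    return expand(a, b)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
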