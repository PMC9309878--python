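"""Synthetic breeding programs with pedigree-consistent gene-dropped genotypes.

The generator emulates a multi-ecoregion inbred breeding program: founder
landraces per ecoregion with diverged haplotype frequencies, generations of
crossing with occasional cross-region parents, a fraction of pure-line
selections, and genotypes produced by dropping founder haplotypes down the
pedigree.  Lines are fully inbred: a cross child draws each LD block from
one parent and is instantly homozygous, matching the homozygosity assumed
by the pedigree-contribution rules.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import (
    BreedingMethod,
    CultivarRecord,
    Ecoregion,
    PedigreeGraph,
    Period,
)
from .snp import SNPMatrix

__all__ = [
    "SimConfig",
    "FounderHaplotypes",
    "SimOutput",
    "simulate_breeding_program",
    "simulate_founder_haplotypes",
    "gene_drop",
    "drop_founder_labels",
    "simulate_program",
]

_REGION_POOL = (Ecoregion.NNC, Ecoregion.HHH, Ecoregion.SC, Ecoregion.FOREIGN)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic breeding program.

    Defaults emulate a three-ecoregion program with mostly-local crossing,
    moderate founder divergence and LD blocks a few SNPs long.
    """

    n_regions: int = 3
    founders_per_region: int = 8
    generations: int = 4
    crosses_per_generation: int = 20
    selection_fraction: float = 0.1
    migration_rate: float = 0.05
    divergence: float = 0.6
    n_chromosomes: int = 2
    snps_per_chromosome: int = 120
    block_length_mean: int = 5
    recomb_per_block: float = 0.01
    mutation_site_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_regions <= len(_REGION_POOL):
            raise ValueError(f"n_regions must lie in [1, {len(_REGION_POOL)}]")
        for name in ("founders_per_region", "n_chromosomes", "snps_per_chromosome", "block_length_mean"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("generations", "crosses_per_generation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("selection_fraction", "migration_rate", "divergence", "recomb_per_block", "mutation_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    @property
    def regions(self) -> tuple[Ecoregion, ...]:
        return _REGION_POOL[: self.n_regions]


@dataclass(frozen=True)
class FounderHaplotypes:
    """Founder SNP haplotypes with the block structure that generated them."""

    sites: pd.DataFrame  # chrom, pos, ref, alt
    block_spans: tuple[tuple[int, int], ...]  # inclusive site-index spans
    haplotypes: Mapping[str, np.ndarray]  # founder id -> alleles (0/1)


@dataclass(frozen=True)
class SimOutput:
    graph: PedigreeGraph
    founders: FounderHaplotypes
    snps: SNPMatrix
    truth: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def simulate_breeding_program(cfg: SimConfig) -> PedigreeGraph:
    """Generate the pedigree of one breeding program (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    records: list[CultivarRecord] = []
    pools: dict[Ecoregion, list[str]] = {r: [] for r in cfg.regions}
    for r in cfg.regions:
        for i in range(cfg.founders_per_region):
            fid = f"{r.value}_F{i + 1:02d}"
            records.append(
                CultivarRecord(id=fid, name=fid, ecoregion=r, period=Period.UNKNOWN)
            )
            pools[r].append(fid)

    for gen in range(1, cfg.generations + 1):
        period = Period.P2006_2015 if gen == cfg.generations else Period.P1923_2005
        new_children: list[tuple[Ecoregion, str]] = []
        for c in range(cfg.crosses_per_generation):
            r = cfg.regions[rng.integers(cfg.n_regions)]
            if len(pools[r]) < 2 and cfg.n_regions < 2:
                raise ValueError("need at least two lines per region to cross")
            female = pools[r][rng.integers(len(pools[r]))]
            if cfg.n_regions > 1 and (
                len(pools[r]) < 2 or rng.random() < cfg.migration_rate
            ):
                other = [q for q in cfg.regions if q is not r]
                r2 = other[rng.integers(len(other))]
                male = pools[r2][rng.integers(len(pools[r2]))]
            else:
                male = pools[r][rng.integers(len(pools[r]))]
                while male == female:
                    male = pools[r][rng.integers(len(pools[r]))]
            cid = f"G{gen}_C{c + 1:02d}"
            records.append(
                CultivarRecord(
                    id=cid,
                    name=cid,
                    method=BreedingMethod.CROSS,
                    female_or_source=female,
                    male=male,
                    ecoregion=r,
                    period=period,
                )
            )
            new_children.append((r, cid))
        for r, cid in new_children:
            pools[r].append(cid)
            if rng.random() < cfg.selection_fraction:
                sid = f"{cid}_s"
                records.append(
                    CultivarRecord(
                        id=sid,
                        name=sid,
                        method=BreedingMethod.SELECTION,
                        female_or_source=cid,
                        ecoregion=r,
                        period=period,
                    )
                )
                pools[r].append(sid)
    return PedigreeGraph(records)


def _distinct_binary_strings(rng: np.random.Generator, length: int, n: int) -> list[np.ndarray]:
    """Up to ``n`` distinct random binary haplotypes of ``length`` sites."""
    n = min(n, 2**min(length, 30))
    out: list[np.ndarray] = []
    seen: set[bytes] = set()
    while len(out) < n:
        h = rng.integers(0, 2, size=length, dtype=np.int8)
        key = h.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def simulate_founder_haplotypes(
    cfg: SimConfig, founder_regions: Mapping[str, Ecoregion] | None = None
) -> FounderHaplotypes:
    """Founder haplotypes with LD-block structure and regional divergence.

    Sites are organized into blocks of geometrically distributed length
    (mean ``block_length_mean``); each block carries two widespread
    haplotypes plus one private haplotype per region.  The ``divergence``
    parameter scales both the private-haplotype frequency and the
    region-to-region perturbation of the widespread-haplotype frequencies:
    at 0 all regions share one frequency profile (no SPA structure beyond
    sampling noise), at 1 half of every region's draws are region-private.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if founder_regions is None:
        founder_regions = {
            f"{r.value}_F{i + 1:02d}": r
            for r in cfg.regions
            for i in range(cfg.founders_per_region)
        }
    n_sites = cfg.n_chromosomes * cfg.snps_per_chromosome
    sites = pd.DataFrame(
        {
            "chrom": [
                f"chr{c + 1}"
                for c in range(cfg.n_chromosomes)
                for _ in range(cfg.snps_per_chromosome)
            ],
            "pos": [
                100 * (j + 1)
                for _ in range(cfg.n_chromosomes)
                for j in range(cfg.snps_per_chromosome)
            ],
            "ref": "A",
            "alt": "T",
        }
    )

    spans: list[tuple[int, int]] = []
    for c in range(cfg.n_chromosomes):
        start = c * cfg.snps_per_chromosome
        end_chrom = start + cfg.snps_per_chromosome
        j = start
        while j < end_chrom:
            length = int(min(1 + rng.geometric(1.0 / cfg.block_length_mean) - 1, end_chrom - j))
            length = max(length, 1)
            spans.append((j, j + length - 1))
            j += length

    regions = cfg.regions
    haps = {f: np.empty(n_sites, dtype=np.int8) for f in founder_regions}
    w_private = 0.5 * cfg.divergence
    for s, e in spans:
        length = e - s + 1
        cands = _distinct_binary_strings(rng, length, 2 + len(regions))
        common = cands[:2]
        private = {
            r: cands[2 + i] if 2 + i < len(cands) else cands[i % len(cands)]
            for i, r in enumerate(regions)
        }
        base = rng.dirichlet(np.ones(len(common)) * 4)
        region_w = {}
        for r in regions:
            pert = rng.dirichlet(np.ones(len(common)))
            w_common = (1 - cfg.divergence) * base + cfg.divergence * pert
            w_common = w_common / w_common.sum() * (1 - w_private)
            region_w[r] = np.append(w_common, w_private)
        for f, r in founder_regions.items():
            weights = region_w.get(r, region_w[regions[0]])
            choice = rng.choice(len(common) + 1, p=weights)
            hap = (
                common[choice]
                if choice < len(common)
                else private.get(r, private[regions[0]])
            )
            haps[f][s : e + 1] = hap
    return FounderHaplotypes(
        sites=sites, block_spans=tuple(spans), haplotypes=haps
    )


def gene_drop(
    graph: PedigreeGraph,
    founders: FounderHaplotypes,
    recomb_per_block: float = 0.01,
    seed: int = 0,
    mutation_site_fraction: float = 0.0,
) -> SNPMatrix:
    """Drop founder haplotypes down the pedigree to genotype every cultivar.

    A cross child inherits each block from the female or male parent with
    probability 1/2 (independently per block); with probability
    ``recomb_per_block`` a within-block crossover splices the two parental
    block haplotypes instead.  Selection copies the source; mutation copies
    then flips ``mutation_site_fraction`` of sites.  Lines are homozygous,
    so calls are 0/2 alt-allele counts.
    """
    rng = np.random.default_rng(seed)
    spans = founders.block_spans
    n_sites = len(founders.sites)
    alleles: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        rec = graph.record(node)
        if rec.is_terminal:
            if node not in founders.haplotypes:
                raise ValueError(f"founder {node!r} has no haplotype")
            alleles[node] = founders.haplotypes[node].copy()
        elif rec.method is BreedingMethod.CROSS:
            fem, mal = (alleles[p] for p in rec.parents)
            child = np.empty(n_sites, dtype=np.int8)
            pick_female = rng.random(len(spans)) < 0.5
            recomb = rng.random(len(spans)) < recomb_per_block
            for b, (s, e) in enumerate(spans):
                first, second = (fem, mal) if pick_female[b] else (mal, fem)
                if recomb[b] and e > s:
                    cut = s + 1 + rng.integers(e - s)
                    child[s:cut] = first[s:cut]
                    child[cut : e + 1] = second[cut : e + 1]
                else:
                    child[s : e + 1] = first[s : e + 1]
            alleles[node] = child
        else:  # selection / mutation
            child = alleles[rec.parents[0]].copy()
            if rec.method is BreedingMethod.MUTATION and mutation_site_fraction > 0:
                n_flip = rng.binomial(n_sites, mutation_site_fraction)
                if n_flip:
                    idx = rng.choice(n_sites, size=n_flip, replace=False)
                    child[idx] = 1 - child[idx]
            alleles[node] = child
    samples = tuple(sorted(graph.records))
    calls = np.stack([2 * alleles[s] for s in samples]).astype(np.int8)
    return SNPMatrix(samples=samples, sites=founders.sites, calls=calls)


def drop_founder_labels(
    graph: PedigreeGraph, n_reps: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Replicated single-locus gene drop of unique founder labels.

    Every founder carries a private allele; each replicate transmits one
    allele per line down the pedigree (crosses pick a parent uniformly,
    selections copy).  Returns per-cultivar arrays of founder indices with
    shape ``(n_reps,)`` — the Monte-Carlo view of identity by descent.
    """
    rng = np.random.default_rng(seed)
    founder_index = {f: i for i, f in enumerate(graph.terminal_records())}
    labels: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        rec = graph.record(node)
        if rec.is_terminal:
            labels[node] = np.full(n_reps, founder_index[node], dtype=np.int32)
        elif rec.method is BreedingMethod.CROSS:
            fem, mal = (labels[p] for p in rec.parents)
            take_female = rng.random(n_reps) < 0.5
            labels[node] = np.where(take_female, fem, mal)
        else:
            labels[node] = labels[rec.parents[0]].copy()
    return labels


def simulate_program(cfg: SimConfig) -> SimOutput:
    """Full synthetic dataset: pedigree, founder haplotypes, genotypes, truth."""
    from .contribution import nuclear_contribution

    graph = simulate_breeding_program(cfg)
    founder_regions = {
        f: graph.record(f).ecoregion for f in graph.terminal_records()
    }
    founders = simulate_founder_haplotypes(cfg, founder_regions)
    snps = gene_drop(
        graph,
        founders,
        recomb_per_block=cfg.recomb_per_block,
        seed=cfg.seed + 2,
        mutation_site_fraction=cfg.mutation_site_fraction,
    )
    truth = {c: nuclear_contribution(graph, c) for c in graph.records}
    return SimOutput(graph=graph, founders=founders, snps=snps, truth=truth)
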