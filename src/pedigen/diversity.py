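"""Genetic richness, allele-frequency dispersion, SPA/SDA and CGS.

All statistics operate on a :class:`~pedigen.ldblock.HaplotypeGenotypeMatrix`
whose loci are multi-allelic haplotype blocks.  Richness counts distinct
haplotypes observed in a subset; dispersion uses the sample-size-corrected
heterozygosity pi = n/(n-1) * sum_i p_i (1 - p_i); SPA/SDA count alleles
private to, or absent only from, one subpopulation; CGS is the identity-by-
state fraction of shared alleles s_ij = sum_k C_ijk / (2 m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ldblock import HaplotypeGenotypeMatrix

__all__ = [
    "DiversitySummary",
    "richness_summary",
    "pi_dispersion",
    "spa_sda",
    "cgs_matrix",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Richness and dispersion summary of one (sub)population."""

    label: str
    n_samples: int
    n_loci: int
    total_alleles: int  # distinct haplotypes summed over loci
    per_locus_mean: float
    per_locus_max: int
    allele_load: float  # total_alleles / n_samples
    pi_mean: float | None = None
    pi_max: float | None = None
    spa: int | None = None
    sda: int | None = None

    def as_row(self) -> dict:
        return {
            "population": self.label,
            "n_cultivars": self.n_samples,
            "allele_total": self.total_alleles,
            "allele_per_locus": self.per_locus_mean,
            "allele_max_per_locus": self.per_locus_max,
            "allele_load": self.allele_load,
            "pi_mean": self.pi_mean,
            "pi_max": self.pi_max,
            "spa": self.spa,
            "sda": self.sda,
        }


def _observed_allele_sets(
    g: HaplotypeGenotypeMatrix, rows: np.ndarray
) -> list[np.ndarray]:
    """Distinct haplotype indices observed per locus among ``rows``."""
    sub = g.genotype[rows]
    return [np.unique(col[col >= 0]) for col in sub.T]


def richness_summary(
    g: HaplotypeGenotypeMatrix,
    subset: Sequence[str],
    label: str = "population",
    with_pi: bool = True,
) -> DiversitySummary:
    """Allele-number richness of ``subset`` (optionally with mean/max pi)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    rows = g.sample_index(subset)
    per_locus = np.array([s.size for s in _observed_allele_sets(g, rows)])
    total = int(per_locus.sum())
    pi_mean = pi_max = None
    if with_pi and len(subset) >= 2:
        pis, pi_mean = pi_dispersion(g, subset)
        pi_max = float(pis.max()) if pis.size else 0.0
    return DiversitySummary(
        label=label,
        n_samples=len(subset),
        n_loci=g.n_loci,
        total_alleles=total,
        per_locus_mean=total / g.n_loci if g.n_loci else 0.0,
        per_locus_max=int(per_locus.max()) if per_locus.size else 0,
        allele_load=total / len(subset),
        pi_mean=pi_mean,
        pi_max=pi_max,
    )


def pi_dispersion(
    g: HaplotypeGenotypeMatrix, subset: Sequence[str]
) -> tuple[np.ndarray, float]:
    """Per-locus and mean allele-frequency dispersion pi of ``subset``.

    pi = n/(n-1) * sum_i p_i (1 - p_i) with haplotype frequencies taken over
    the non-missing subset members at each locus; the population value is
    the unweighted mean over loci.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("pi requires at least two samples")
    rows = g.sample_index(subset)
    sub = g.genotype[rows]
    pis = np.zeros(g.n_loci)
    for k in range(g.n_loci):
        col = sub[:, k]
        col = col[col >= 0]
        n = col.size
        if n < 2:
            continue
        freqs = np.bincount(col) / n
        pis[k] = n / (n - 1) * float((freqs * (1 - freqs)).sum())
    return pis, float(pis.mean()) if pis.size else 0.0


def spa_sda(
    g: HaplotypeGenotypeMatrix, partition: Mapping[str, str]
) -> pd.DataFrame:
    """Specific present / specific deficient allele counts per population.

    ``partition`` maps sample id -> population label.  An allele (locus,
    haplotype) is SPA of population P when observed in P and in no other
    population; SDA of P when absent from P but present in *all* other
    populations.
    """
    pops = sorted(set(partition.values()))
    if len(pops) < 2:
        raise ValueError("SPA/SDA require at least two populations")
    members = {p: [s for s, q in partition.items() if q == p] for p in pops}
    presence = {
        p: _observed_allele_sets(g, g.sample_index(members[p])) for p in pops
    }
    spa = dict.fromkeys(pops, 0)
    sda = dict.fromkeys(pops, 0)
    for k in range(g.n_loci):
        sets = {p: set(presence[p][k].tolist()) for p in pops}
        for p in pops:
            others = [sets[q] for q in pops if q != p]
            union_others = set().union(*others)
            inter_others = set.intersection(*others)
            spa[p] += len(sets[p] - union_others)
            sda[p] += len(inter_others - sets[p])
    return pd.DataFrame(
        {"population": pops, "spa": [spa[p] for p in pops], "sda": [sda[p] for p in pops]}
    ).set_index("population")


def cgs_matrix(g: HaplotypeGenotypeMatrix, subset: Sequence[str]) -> pd.DataFrame:
    """Coefficient-of-genetic-similarity matrix (identity by state).

    For homozygous lines the common-allele count at a locus is 2 when the
    haplotypes match and 0 otherwise, so s_ij is the fraction of
    pairwise-complete loci with matching haplotypes.  Pairs with no
    overlapping non-missing loci get NaN.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    rows = g.sample_index(subset)
    sub = g.genotype[rows]
    valid = sub >= 0
    n = len(subset)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                vals[i, j] = vals[j, i] = np.nan
                continue
            s = float((sub[i, both] == sub[j, both]).mean())
            vals[i, j] = vals[j, i] = s
    return pd.DataFrame(vals, index=subset, columns=subset)
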