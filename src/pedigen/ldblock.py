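"""SNP linkage-disequilibrium blocks (SNPLDBs) as multi-allelic haplotype loci.

Adjacent SNPs in strong LD (|D'| above a threshold) are grouped into blocks;
each block becomes one locus whose alleles are the haplotypes observed among
the (inbred, hence effectively phased) samples.  Blocking is greedy
left-to-right within a chromosome: a site joins the current block only while
its pairwise |D'| with *every* site already in the block exceeds the
threshold.  Haplotype classes rarer than a frequency floor are merged into a
single catch-all class.

The exact blocking used by association-scale pipelines differs in details
(window limits, merge order); a pre-assembled haplotype-locus matrix can be
supplied directly via :func:`read_haplotype_matrix` when fidelity to an
external block map matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .snp import MISSING, SNPMatrix

__all__ = [
    "HaplotypeGenotypeMatrix",
    "dprime",
    "assemble_snpldb",
    "write_block_map",
    "write_haplotype_matrix",
    "read_haplotype_matrix",
]

RARE_LABEL = "RARE"

BLOCK_COLUMNS = ("chrom", "start_idx", "end_idx", "start_pos", "end_pos", "n_haplotypes")


@dataclass(frozen=True)
class HaplotypeGenotypeMatrix:
    """Samples x haplotype-locus matrix (one multi-allelic locus per block).

    ``genotype[i, k]`` indexes block ``k``'s haplotype catalog (homozygous
    lines carry a single index); -1 marks missing.  ``catalogs[k]`` lists
    ``(haplotype_string, frequency)`` pairs; frequencies are taken over
    non-missing samples and sum to 1.
    """

    samples: tuple[str, ...]
    blocks: pd.DataFrame  # columns per BLOCK_COLUMNS
    catalogs: tuple[tuple[tuple[str, float], ...], ...]
    genotype: np.ndarray  # int32, (n_samples, n_blocks); -1 missing

    def __post_init__(self) -> None:
        if self.genotype.shape != (len(self.samples), len(self.blocks)):
            raise ValueError("genotype shape does not match samples x blocks")
        for k, cat in enumerate(self.catalogs):
            col = self.genotype[:, k]
            if col.max(initial=-1) >= len(cat):
                raise ValueError(f"block {k}: genotype index beyond catalog")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.blocks)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown sample id {err.args[0]!r}") from None


def dprime(h1: np.ndarray, h2: np.ndarray) -> float:
    """Standardized LD |D'| between two biallelic sites from haplotypes.

    ``h1``/``h2`` are allele vectors (0/1, -1 missing) over the same
    samples; pairwise-complete observations are used.  Returns 0 when either
    site is monomorphic among the complete pairs (no LD information).
    """
    ok = (h1 >= 0) & (h2 >= 0)
    a, b = h1[ok].astype(float), h2[ok].astype(float)
    if a.size == 0:
        return 0.0
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0
    pab = (a * b).mean()
    d = pab - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax == 0:
        return 0.0
    return abs(d) / dmax


def _haplotype_alleles(m: SNPMatrix) -> np.ndarray:
    """Per-site haplotype alleles of inbred lines: 0/1, -1 missing."""
    calls = m.calls
    out = np.full(calls.shape, -1, dtype=np.int8)
    out[calls == 0] = 0
    out[calls == 2] = 1
    # residual heterozygous calls carry no phased haplotype -> missing
    return out


def assemble_snpldb(
    m: SNPMatrix,
    dprime_threshold: float = 0.7,
    rare_floor: float = 0.01,
) -> HaplotypeGenotypeMatrix:
    """Partition SNPs into LD blocks and recode samples as haplotype indices.

    ``dprime_threshold`` is the |D'| a candidate site must exceed with every
    site of the current block to join it; ``rare_floor`` is the haplotype
    frequency below which classes are merged into one rare class (merging
    happens only when two or more classes fall below the floor).
    """
    if not 0.0 < dprime_threshold <= 1.0:
        raise ValueError(f"dprime_threshold must lie in (0, 1], got {dprime_threshold!r}")
    if m.n_sites == 0:
        raise ValueError("cannot assemble blocks from an empty SNP matrix")
    alleles = _haplotype_alleles(m)
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()

    block_spans: list[tuple[int, int]] = []  # inclusive site-index spans
    start = 0
    for j in range(1, m.n_sites + 1):
        if j == m.n_sites or chroms[j] != chroms[start]:
            block_spans.append((start, j - 1))
            start = j
            continue
        in_ld = all(
            dprime(alleles[:, t], alleles[:, j]) > dprime_threshold
            for t in range(start, j)
        )
        if not in_ld:
            block_spans.append((start, j - 1))
            start = j

    rows = []
    catalogs: list[tuple[tuple[str, float], ...]] = []
    geno = np.full((m.n_samples, len(block_spans)), -1, dtype=np.int32)
    for k, (s, e) in enumerate(block_spans):
        sub = alleles[:, s : e + 1]
        complete = (sub >= 0).all(axis=1)
        strings = np.array(
            ["".join(map(str, row)) for row in sub], dtype=object
        )
        obs = strings[complete]
        cats, counts = np.unique(obs, return_counts=True)
        freqs = counts / counts.sum() if counts.size else counts.astype(float)
        order = np.argsort(-freqs, kind="stable")
        cats, freqs = cats[order], freqs[order]
        rare = freqs < rare_floor
        if rare.sum() >= 2:
            kept = [(str(c), float(f)) for c, f in zip(cats[~rare], freqs[~rare])]
            kept.append((RARE_LABEL, float(freqs[rare].sum())))
            index_of = {c: i for i, (c, _) in enumerate(kept[:-1])}
            rare_idx = len(kept) - 1
            catalog = tuple(kept)
        else:
            catalog = tuple((str(c), float(f)) for c, f in zip(cats, freqs))
            index_of = {c: i for i, (c, _) in enumerate(catalog)}
            rare_idx = None
        for i in np.flatnonzero(complete):
            s_i = strings[i]
            geno[i, k] = index_of.get(s_i, rare_idx if rare_idx is not None else -1)
        catalogs.append(catalog)
        rows.append(
            (chroms[s], s, e, pos[s], pos[e], len(catalog))
        )
    blocks = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    return HaplotypeGenotypeMatrix(
        samples=m.samples,
        blocks=blocks,
        catalogs=tuple(catalogs),
        genotype=geno,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_block_map(g: HaplotypeGenotypeMatrix, path: str | Path) -> None:
    """BED-like block map: chrom, start, end (0-based half-open), n_haplotypes."""
    df = pd.DataFrame(
        {
            "chrom": g.blocks["chrom"],
            "start": g.blocks["start_pos"] - 1,
            "end": g.blocks["end_pos"],
            "n_haplotypes": g.blocks["n_haplotypes"],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def write_haplotype_matrix(g: HaplotypeGenotypeMatrix, path: str | Path) -> None:
    """Samples x loci haplotype-index matrix as TSV (-1 = missing)."""
    loci = [
        f"{b.chrom}:{b.start_pos}-{b.end_pos}" for b in g.blocks.itertuples(index=False)
    ]
    pd.DataFrame(g.genotype, index=list(g.samples), columns=loci).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_haplotype_matrix(path: str | Path) -> HaplotypeGenotypeMatrix:
    """Load a pre-assembled haplotype-locus matrix (TSV, -1 = missing).

    Block coordinates are parsed from column names of the form
    ``chrom:start-end``; unparsable names become synthetic single-site
    blocks.  Catalog entries are synthesized from the observed index range
    (haplotype strings are not recoverable from an index matrix).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    geno = df.to_numpy(dtype=np.int32)
    rows = []
    catalogs = []
    for k, name in enumerate(df.columns):
        try:
            chrom, span = str(name).split(":")
            start_s, end_s = span.split("-")
            chrom_v, start_v, end_v = chrom, int(start_s), int(end_s)
        except ValueError:
            chrom_v, start_v, end_v = str(name), k + 1, k + 1
        col = geno[:, k]
        valid = col[col >= 0]
        n_h = int(valid.max()) + 1 if valid.size else 0
        freqs = (
            np.bincount(valid, minlength=n_h) / valid.size if valid.size else np.array([])
        )
        catalogs.append(tuple((f"h{i}", float(freqs[i])) for i in range(n_h)))
        rows.append((chrom_v, k, k, start_v, end_v, n_h))
    blocks = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    return HaplotypeGenotypeMatrix(
        samples=tuple(str(s) for s in df.index),
        blocks=blocks,
        catalogs=tuple(catalogs),
        genotype=geno,
    )
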