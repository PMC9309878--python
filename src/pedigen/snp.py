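"""Biallelic SNP genotype matrix: container, VCF I/O and quality control.

Genotypes are stored as alt-allele counts (0, 1, 2) with -1 for missing, in
a samples x sites int8 array.  The expected input is resequencing-derived
biallelic SNP calls on inbred lines, so heterozygous calls are rare and can
optionally be recoded as missing before frequency-based filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SNPMatrix", "read_vcf", "write_vcf", "qc_filter_snps"]

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass(frozen=True)
class SNPMatrix:
    """Samples x sites matrix of biallelic SNP calls (alt-allele counts)."""

    samples: tuple[str, ...]
    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    calls: np.ndarray  # int8, shape (n_samples, n_sites); -1 = missing

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for _, chrom_sites in self.sites.groupby("chrom", sort=False):
            pos = chrom_sites["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on {chrom_sites['chrom'].iat[0]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "SNPMatrix":
        return SNPMatrix(
            samples=self.samples,
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown sample id {err.args[0]!r}") from None


def read_vcf(path: str | Path) -> SNPMatrix:
    """Read biallelic SNPs from a VCF (v4.x) file into an :class:`SNPMatrix`.

    Multi-allelic or non-SNP records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    rows: list[tuple] = []
    calls: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = np.asarray(var.gt_types)
        code = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING)))
        calls.append(code.astype(np.int8))
    vcf.close()
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-biallelic-SNP records")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    arr = (
        np.stack(calls, axis=1)
        if calls
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return SNPMatrix(samples=samples, sites=sites, calls=arr)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(m: SNPMatrix, path: str | Path, source: str = "pedigen") -> None:
    """Write the matrix as minimal VCFv4.2 text (GT field only)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(m.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for j, site in enumerate(m.sites.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in m.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def qc_filter_snps(
    m: SNPMatrix,
    max_missing: float = 0.2,
    max_het: float = 0.1,
    min_maf: float = 0.01,
    het_to_missing: bool = True,
) -> SNPMatrix:
    """Drop sites failing missing-rate, heterozygosity or MAF thresholds.

    Rules (a site is dropped if it fails any): missing rate <= ``max_missing``,
    heterozygous-call rate <= ``max_het``, minor allele frequency >=
    ``min_maf``.  With ``het_to_missing`` (default) heterozygous calls are
    recoded missing *before* allele frequencies are computed, matching a
    workflow in which residual heterozygosity in inbred lines is treated as
    call error.
    """
    for name, v in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    calls = m.calls
    n = m.n_samples
    miss_rate = (calls == MISSING).sum(axis=0) / n
    het_rate = (calls == 1).sum(axis=0) / n
    work = np.where(calls == 1, MISSING, calls) if het_to_missing else calls
    valid = work != MISSING
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(work == MISSING, 0, work).sum(axis=0) / (2.0 * n_valid)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf = np.where(n_valid == 0, 0.0, maf)
    keep = (miss_rate <= max_missing) & (het_rate <= max_het) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("QC removed every site")
    out = m.take_sites(np.flatnonzero(keep))
    if het_to_missing:
        out = SNPMatrix(
            samples=out.samples,
            sites=out.sites,
            calls=np.where(out.calls == 1, MISSING, out.calls).astype(np.int8),
        )
    return out
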