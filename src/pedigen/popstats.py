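"""Population differentiation and structure: Weir-Cockerham F_ST, Mantel, PCA.

The F_ST estimator follows the variance-component form
``F_ST = sum_u a_u / sum_u (a_u + b_u + c_u)`` where, for every allele u at
every locus, a, b and c are the variance components between subpopulations,
between individuals within subpopulations and between gametes within
individuals.  Components are summed over all alleles and loci before the
ratio (negative per-locus components retained).  Fully homozygous lines have
zero observed heterozygosity, so the gamete-within-individual component
vanishes for inbred data.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .ldblock import HaplotypeGenotypeMatrix

__all__ = ["fst_weir_cockerham", "mantel_test", "pca_coordinates"]


class MonomorphicError(ValueError):
    """All loci monomorphic: the differentiation estimator is undefined."""


def _wc_components(
    counts: np.ndarray, het_counts: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Weir-Cockerham a/b/c sums for one locus.

    ``counts``: populations x alleles matrix of *individual* counts (each
    homozygous individual counted once per its allele).  ``het_counts``:
    populations x alleles heterozygote counts (zero for inbred lines).
    """
    n_i = counts.sum(axis=1).astype(float)
    r = counts.shape[0]
    nbar = n_i.mean()
    if nbar <= 1 or (n_i < 1).any():
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc == 0:
        return 0.0, 0.0, 0.0
    if het_counts is None:
        het_counts = np.zeros_like(counts)
    a_sum = b_sum = c_sum = 0.0
    for u in range(counts.shape[1]):
        p_i = counts[:, u] / n_i
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = het_counts[:, u].sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum, b_sum, c_sum


def fst_weir_cockerham(
    g: HaplotypeGenotypeMatrix, pop_a: Sequence[str], pop_b: Sequence[str]
) -> float:
    """Multi-allelic Weir-Cockerham F_ST between two subpopulations.

    The raw ratio-of-sums estimator is returned (it can be slightly
    negative when there is no differentiation); clamping for display is the
    caller's choice.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least two samples")
    rows = [g.sample_index(pop_a), g.sample_index(pop_b)]
    num = den = 0.0
    for k in range(g.n_loci):
        cols = [g.genotype[r, k] for r in rows]
        cols = [c[c >= 0] for c in cols]
        if any(c.size < 2 for c in cols):
            continue
        n_alleles = int(max(c.max() for c in cols)) + 1
        if n_alleles < 2:
            continue
        counts = np.stack([np.bincount(c, minlength=n_alleles) for c in cols])
        a, b, c_ = _wc_components(counts)
        num += a
        den += a + b + c_
    if den == 0.0:
        raise MonomorphicError(
            "every informative locus is monomorphic; F_ST is undefined"
        )
    return num / den


def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    m1: pd.DataFrame | np.ndarray,
    m2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel permutation test between two symmetric matrices.

    Returns ``(r, p)``: the Pearson correlation of the off-diagonal upper
    triangles and the permutation tail probability with the
    ``(count + 1) / (n_perm + 1)`` correction.  When the inputs are
    DataFrames their ids must match in order.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix shapes {a.shape} and {b.shape} do not match")
    if isinstance(m1, pd.DataFrame) and isinstance(m2, pd.DataFrame):
        if list(m1.index) != list(m2.index):
            raise ValueError("matrix ids must match in order")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = _offdiag_upper(a)
    r_obs = float(np.corrcoef(x, _offdiag_upper(b))[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = float(np.corrcoef(x, _offdiag_upper(b[np.ix_(perm, perm)]))[0, 1])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        else:  # two-sided
            count += abs(r_p) >= abs(r_obs)
    return r_obs, (count + 1) / (n_perm + 1)


def one_hot_encoding(g: HaplotypeGenotypeMatrix) -> np.ndarray:
    """Column-centered one-hot haplotype encoding (missing -> column mean)."""
    blocks = []
    for k in range(g.n_loci):
        col = g.genotype[:, k]
        n_h = len(g.catalogs[k])
        if n_h == 0:
            continue
        onehot = np.zeros((g.n_samples, n_h))
        obs = col >= 0
        onehot[np.flatnonzero(obs), col[obs]] = 1.0
        mean = onehot[obs].mean(axis=0) if obs.any() else np.zeros(n_h)
        onehot[~obs] = mean
        blocks.append(onehot - mean)
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((g.n_samples, 0))


def pca_coordinates(
    g: HaplotypeGenotypeMatrix, n_components: int = 3
) -> pd.DataFrame:
    """Principal-component scores from the one-hot haplotype encoding.

    Components follow a fixed sign convention: the largest-magnitude loading
    of each component is made positive.  If ``n_components`` exceeds the
    matrix rank the result is truncated with a warning.
    """
    if g.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    x = one_hot_encoding(g)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = rank
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores,
        index=list(g.samples),
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
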