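"""Neighbor-joining clustering of cultivars from genetic-distance matrices.

The tree is built with the canonical Saitou-Nei agglomeration (Q-matrix
minimization with the standard branch-length formulas).  Determinism is
pinned down: Q ties resolve to the lowest index pair, and a negative branch
length is clamped to zero with the deficit transferred to its sibling edge
so leaf-to-leaf path lengths are preserved.  Groups are delimited by cutting
the longest edges of the midpoint-rooted tree, internal edges first.
"""

from __future__ import annotations

import itertools
import string
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "nj_tree",
    "assign_groups",
    "group_by_region_table",
    "leaf_root_distances",
    "write_newick",
]


def _check_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    vals = d.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal must be zero")
    if (vals < -1e-12).any():
        raise ValueError("distances must be nonnegative")
    return vals


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Unrooted neighbor-joining tree from a genetic-distance matrix."""
    vals = _check_distance_matrix(d)
    ids = [str(i) for i in d.index]
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    dm = vals.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: ties resolve to the lowest index pair
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i_loc], active[j_loc]
        child_i, child_j = nodes[gi], nodes[gj]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to every remaining cluster
        new_row = 0.5 * (dm[gi, :] + dm[gj, :] - dij)
        dm = np.vstack([dm, new_row])
        new_col = np.append(new_row, 0.0)
        dm = np.column_stack([dm, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    gi, gj = active
    a, b = nodes[gi], nodes[gj]
    dab = max(float(dm[gi, gj]), 0.0)
    # the final edge is split at its middle to host the (arbitrary) root
    a.length = dab / 2
    b.length = dab / 2
    return TreeNode(children=[a, b])


def _smallest_leaf(node: TreeNode) -> str:
    return min(t.name for t in node.tips()) if not node.is_tip() else node.name


def assign_groups(tree: TreeNode, k: int) -> dict[str, str]:
    """Cut the midpoint-rooted tree into ``k`` leaf groups.

    The k-1 longest edges are removed greedily (internal edges before leaf
    edges; ties broken by the smallest leaf name below the edge), skipping
    cuts that would strand a leafless component.  Groups are labelled
    A, B, ... by decreasing size, then by their lexicographically smallest
    member.
    """
    leaves = [t.name for t in tree.tips()]
    n = len(leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    work = tree.copy()
    if n > 2:
        try:
            work = work.root_at_midpoint()
        except Exception:  # zero-length corner cases: keep the given rooting
            pass

    candidates = sorted(
        (node for node in work.traverse() if node is not work),
        key=lambda nd: (
            nd.is_tip(),  # internal edges first
            -(nd.length or 0.0),
            _smallest_leaf(nd),
        ),
    )
    cuts: list[TreeNode] = []

    def leaf_groups(cut_set: list[TreeNode]) -> dict[str, frozenset[str]]:
        marked = set(map(id, cut_set))
        groups: dict[str, set[str]] = {}
        for tip in work.tips():
            anchor = "__root__"
            node = tip
            while node is not None:
                if id(node) in marked:
                    anchor = str(id(node))
                    break
                node = node.parent
            groups.setdefault(anchor, set()).add(tip.name)
        return {k_: frozenset(v) for k_, v in groups.items()}

    for cand in candidates:
        if len(leaf_groups(cuts)) >= k:
            break
        trial = cuts + [cand]
        if len(leaf_groups(trial)) > len(leaf_groups(cuts)):
            cuts = trial
    groups = sorted(
        leaf_groups(cuts).values(), key=lambda g: (-len(g), min(g))
    )
    labels = _group_labels(len(groups))
    return {leaf: labels[gi] for gi, grp in enumerate(groups) for leaf in grp}


def _group_labels(n: int) -> list[str]:
    singles = list(string.ascii_uppercase)
    doubles = ("".join(p) for p in itertools.product(singles, repeat=2))
    return list(itertools.islice(itertools.chain(singles, doubles), n))


def group_by_region_table(
    groups: Mapping[str, str], regions: Mapping[str, str]
) -> pd.DataFrame:
    """Region x group contingency table with margins (row/column totals)."""
    if set(groups) != set(regions):
        raise ValueError("group and region maps must cover the same ids")
    ids = sorted(groups)
    df = pd.DataFrame(
        {"region": [regions[i] for i in ids], "group": [groups[i] for i in ids]}
    )
    return pd.crosstab(df["region"], df["group"], margins=True, margins_name="Total")


def leaf_root_distances(tree: TreeNode) -> dict[str, float]:
    """Per-leaf distance to the root of a (midpoint-)rooted tree."""
    out: dict[str, float] = {}
    for tip in tree.tips():
        dist = 0.0
        node = tip
        while node.parent is not None:
            dist += node.length or 0.0
            node = node.parent
        out[tip.name] = dist
    return out


def write_newick(tree: TreeNode, path: str | Path, digits: int = 6) -> None:
    """Newick output with branch lengths rounded to ``digits`` significant digits."""
    t = tree.copy()
    for node in t.traverse():
        if node.length is not None:
            node.length = float(f"%.{digits}g" % node.length)
    t.write(str(path), format="newick")
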