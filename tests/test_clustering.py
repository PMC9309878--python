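"""Neighbor joining, tree cutting into groups, and region cross-tabulation."""

import numpy as np
import pandas as pd
import pytest

from pedigen import assign_groups, group_by_region_table, nj_tree, write_newick
from pedigen.clustering import leaf_root_distances


def tree_splits(tree, taxa: frozenset) -> set[frozenset]:
    """Nontrivial unrooted bipartitions of a tree, canonicalized."""
    splits = set()
    for node in tree.traverse():
        if node.parent is None or node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(taxa) - 1:
            other = taxa - below
            splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return splits


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random binary tree with branch lengths; returns (distances, splits)."""
    ids = [f"t{i}" for i in range(n)]
    # each cluster: (set of member leaves, {leaf: distance to cluster root})
    clusters = [({i}, {i: 0.0}) for i in ids]
    dist = pd.DataFrame(0.0, index=ids, columns=ids)
    splits: list[frozenset] = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        (mi, di) = clusters[i]
        (mj, dj) = clusters[j]
        li, lj = rng.uniform(0.5, 1.5, size=2)
        for a in mi:
            for b in mj:
                d = di[a] + li + dj[b] + lj
                dist.loc[a, b] = dist.loc[b, a] = d
        merged = (
            mi | mj,
            {**{a: v + li for a, v in di.items()}, **{b: v + lj for b, v in dj.items()}},
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        if 1 < len(merged[0]) < n - 1:
            splits.append(frozenset(merged[0]))
    taxa = frozenset(ids)
    canon = {min(s, taxa - s, key=lambda x: (len(x), sorted(x))) for s in splits}
    return dist, canon


class TestNJTree:
    def test_two_taxa_single_edge(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = nj_tree(d)
        total = sum(n.length or 0 for n in tree.traverse() if n.parent is not None)
        assert total == pytest.approx(3.0)
        assert {t.name for t in tree.tips()} == {"a", "b"}

    def test_four_taxon_additive_metric_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5))
        ids = list("ABCD")
        d = pd.DataFrame(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            index=ids,
            columns=ids,
            dtype=float,
        )
        tree = nj_tree(d)
        taxa = frozenset(ids)
        assert tree_splits(tree, taxa) == {frozenset({"A", "B"})}
        for a in ids:
            for b in ids:
                if a != b:
                    ta = next(t for t in tree.tips() if t.name == a)
                    tb = next(t for t in tree.tips() if t.name == b)
                    assert ta.distance(tb) == pytest.approx(d.loc[a, b])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_additive_trees_recovered(self, seed, n):
        rng = np.random.default_rng(1000 * n + seed)
        d, expected_splits = random_additive_tree(rng, n)
        tree = nj_tree(d)
        assert tree_splits(tree, frozenset(d.index)) == expected_splits
        # and the metric is reproduced
        tips = {t.name: t for t in tree.tips()}
        for a in d.index:
            for b in d.index:
                if a != b:
                    assert tips[a].distance(tips[b]) == pytest.approx(d.loc[a, b])

    @pytest.mark.parametrize("seed", range(3))
    def test_topology_matches_reference_implementation(self, seed):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        a = rng.random((8, 8))
        vals = (a + a.T) / 2
        np.fill_diagonal(vals, 0.0)
        ids = [f"x{i}" for i in range(8)]
        d = pd.DataFrame(vals, index=ids, columns=ids)
        ours = nj_tree(d)
        ref = skbio_nj(DistanceMatrix(vals, ids))
        taxa = frozenset(ids)
        assert tree_splits(ours, taxa) == tree_splits(ref, taxa)

    def test_leaf_multiset_preserved_and_row_order_invariant_length(self):
        rng = np.random.default_rng(0)
        a = rng.random((7, 7))
        vals = (a + a.T) / 2
        np.fill_diagonal(vals, 0.0)
        ids = [f"x{i}" for i in range(7)]
        d = pd.DataFrame(vals, index=ids, columns=ids)
        t1 = nj_tree(d)
        perm = rng.permutation(7)
        d2 = d.iloc[perm, perm]
        t2 = nj_tree(d2)
        assert sorted(t.name for t in t1.tips()) == sorted(t.name for t in t2.tips())
        len1 = sum(n.length or 0 for n in t1.traverse() if n.parent is not None)
        len2 = sum(n.length or 0 for n in t2.traverse() if n.parent is not None)
        assert len1 == pytest.approx(len2)

    def test_single_taxon_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_newick_output_readable(self, tmp_path):
        from skbio import TreeNode

        rng = np.random.default_rng(1)
        d, _ = random_additive_tree(rng, 6)
        tree = nj_tree(d)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = TreeNode.read(str(path))
        assert {t.name for t in back.tips()} == set(d.index)


class TestAssignGroups:
    @staticmethod
    def _planted_distance(rng, sizes: dict[str, int], within=0.1, between=1.0):
        ids, labels = [], {}
        for lab, k in sizes.items():
            for i in range(k):
                cid = f"{lab}{i}"
                ids.append(cid)
                labels[cid] = lab
        n = len(ids)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = within if labels[ids[i]] == labels[ids[j]] else between
                vals[i, j] = vals[j, i] = base + rng.uniform(0, 0.02)
        return pd.DataFrame(vals, index=ids, columns=ids), labels

    def test_k1_single_group(self, rng):
        d, _ = self._planted_distance(rng, {"a": 3, "b": 3})
        tree = nj_tree(d)
        groups = assign_groups(tree, 1)
        assert set(groups.values()) == {"A"}

    def test_k_equals_n_singletons(self, rng):
        d, _ = self._planted_distance(rng, {"a": 3, "b": 3})
        tree = nj_tree(d)
        groups = assign_groups(tree, 6)
        assert len(set(groups.values())) == 6

    def test_two_planted_clusters_recovered(self, rng):
        d, labels = self._planted_distance(rng, {"a": 5, "b": 4})
        tree = nj_tree(d)
        groups = assign_groups(tree, 2)
        by_group: dict[str, set] = {}
        for cid, grp in groups.items():
            by_group.setdefault(grp, set()).add(labels[cid])
        assert all(len(v) == 1 for v in by_group.values())

    def test_labels_ordered_by_size(self, rng):
        d, labels = self._planted_distance(rng, {"a": 6, "b": 3})
        groups = assign_groups(nj_tree(d), 2)
        sizes = {}
        for cid, grp in groups.items():
            sizes[grp] = sizes.get(grp, 0) + 1
        assert sizes["A"] == 6 and sizes["B"] == 3

    def test_invalid_k_rejected(self, rng):
        d, _ = self._planted_distance(rng, {"a": 2, "b": 2})
        tree = nj_tree(d)
        with pytest.raises(ValueError):
            assign_groups(tree, 5)

    def test_root_distances_nonnegative(self, rng):
        d, _ = self._planted_distance(rng, {"a": 4, "b": 4})
        tree = nj_tree(d).root_at_midpoint()
        dists = leaf_root_distances(tree)
        assert set(dists) == set(d.index)
        assert all(v >= 0 for v in dists.values())


class TestRegionTable:
    def test_single_cell(self):
        groups = {f"c{i}": "A" for i in range(4)}
        regions = {f"c{i}": "NNC" for i in range(4)}
        t = group_by_region_table(groups, regions)
        assert t.loc["NNC", "A"] == 4
        assert t.loc["Total", "Total"] == 4

    def test_margins_match_label_frequencies(self, rng):
        ids = [f"c{i}" for i in range(30)]
        groups = {i: "ABC"[rng.integers(3)] for i in ids}
        regions = {i: ["NNC", "HHH", "SC"][rng.integers(3)] for i in ids}
        t = group_by_region_table(groups, regions)
        assert t.loc["Total", "Total"] == 30
        for reg in set(regions.values()):
            assert t.loc[reg, "Total"] == sum(r == reg for r in regions.values())
        for grp in set(groups.values()):
            assert t.loc["Total", grp] == sum(g == grp for g in groups.values())

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_by_region_table({"a": "A"}, {"b": "NNC"})
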