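"""Distances, neighbour joining (vs independent oracles) and bootstrap."""

import itertools

import numpy as np
import pytest

from splicekin.cohort import ortholog_alignment
from splicekin.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    nj_tree,
    pairwise_distances,
)


class TestDistances:
    def test_identical_sequences_zero(self):
        dm = pairwise_distances({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm[("a", "b")] == 0.0

    def test_p_distance_simple(self):
        dm = pairwise_distances({"a": "ACGT", "b": "ACGA"}, model="p")
        assert dm[("a", "b")] == 0.25

    def test_k2p_formula(self):
        """10% transitions, 5% transversions over 100 comparable sites."""
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85  # A->G transition, A->C transversion
        d = pairwise_distances({"a": a, "b": b}, model="K2P")[("a", "b")]
        expect = -0.5 * np.log(1 - 0.2 - 0.05) - 0.25 * np.log(1 - 0.1)
        assert d == pytest.approx(expect)

    def test_pairwise_deletion_excludes_ambiguity(self):
        dm = pairwise_distances({"a": "ACGTNNNN", "b": "ACGAAAAA"}, model="p")
        assert dm[("a", "b")] == 0.25  # only 4 comparable sites

    def test_saturation_raises_naming_pair(self):
        with pytest.raises(SaturationError, match="x/y"):
            pairwise_distances({"x": "AAAA", "y": "GGGG"}, model="K2P")

    def test_p_never_exceeds_k2p(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            L = 300
            a = "".join(rng.choice(list("ACGT"), L))
            b = list(a)
            for i in rng.choice(L, size=int(rng.integers(1, 60)), replace=False):
                b[i] = "ACGT"[int(rng.integers(4))]
            aln = {"a": a, "b": "".join(b)}
            p = pairwise_distances(aln, "p")[("a", "b")]
            k = pairwise_distances(aln, "K2P")[("a", "b")]
            assert p <= k + 1e-12


# ---------------------------------------------------------------------------
# minimum-evolution oracle (exhaustive topologies + OLS branch lengths)
# ---------------------------------------------------------------------------

def all_topologies(labels):
    """All unrooted binary topologies as edge lists over labelled leaves."""
    labels = list(labels)
    first = [
        {("i0", labels[0]), ("i0", labels[1]), ("i0", labels[2])}
    ]
    trees = first
    for idx, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        for edges in trees:
            for eidx, edge in enumerate(sorted(edges)):
                rest = edges - {edge}
                mid = f"i{idx}_{eidx}"
                new = rest | {(edge[0], mid), (mid, edge[1]), (mid, leaf)}
                new_trees.append(new)
        trees = new_trees
    return trees


def tree_paths(edges, labels):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edge_list = sorted(edges)
    eidx = {e: i for i, e in enumerate(edge_list)}

    def path(a, b):
        stack = [(a, None, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == b:
                return used
            for nb in adj[node]:
                if nb == prev:
                    continue
                e = (node, nb) if (node, nb) in eidx else (nb, node)
                stack.append((nb, node, used + [eidx[e]]))
        raise RuntimeError

    rows, d_order = [], []
    for a, b in itertools.combinations(labels, 2):
        row = np.zeros(len(edge_list))
        for i in path(a, b):
            row[i] = 1
        rows.append(row)
        d_order.append((a, b))
    return np.array(rows), d_order, edge_list


def min_evolution_tree(dm: DistanceMatrix):
    """Brute-force minimum-evolution: OLS branch lengths on every topology,
    keep the shortest total length; returns its bipartition set."""
    labels = list(dm.labels)
    best = None
    for edges in all_topologies(labels):
        X, order, edge_list = tree_paths(edges, labels)
        d = np.array([dm[pair] for pair in order])
        b, *_ = np.linalg.lstsq(X, d, rcond=None)
        total = b.sum()
        if best is None or total < best[0] - 1e-10:
            best = (total, edges, edge_list, b)
    _, edges, edge_list, b = best
    # bipartitions of internal edges
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u, v):
        out, stack = set(), [(v, u)]
        while stack:
            node, prev = stack.pop()
            if not node.startswith("i"):
                out.add(node)
            for nb in adj[node]:
                if nb != prev:
                    stack.append((nb, node))
        return frozenset(out)

    ref = min(labels)
    bips = set()
    for u, v in edges:
        if u.startswith("i") and v.startswith("i"):
            s = side(u, v)
            s = s if ref not in s else frozenset(labels) - s
            if 2 <= len(s) <= len(labels) - 2:
                bips.add(s)
    return bips


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    labels = [chr(ord("A") + i) for i in range(n)]
    tops = all_topologies(labels)
    edges = tops[int(rng.integers(len(tops)))]
    X, order, edge_list = tree_paths(edges, labels)
    b = rng.uniform(0.5, 3.0, size=len(edge_list))
    d = X @ b
    mat = np.zeros((n, n))
    for (a, c), val in zip(order, d):
        i, j = labels.index(a), labels.index(c)
        mat[i, j] = mat[j, i] = val
    return DistanceMatrix(tuple(labels), mat)


class TestNeighborJoining:
    def test_four_taxa_additive_exact(self):
        labels = ("A", "B", "C", "D")
        mat = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree.is_monophyletic(["A", "B"])
        assert tree.is_monophyletic(["C", "D"])
        # recover leaf branch lengths exactly
        lengths = {}

        def walk(node):
            for c, ln in node.children:
                if not c.children:
                    lengths[c.name] = ln
                walk(c)

        walk(tree.root)
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        mat = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), mat))
        lens = {c.name: ln for c, ln in tree.root.children}
        assert lens == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0.0]])))

    @pytest.mark.parametrize("n", [4, 5])
    def test_equals_minimum_evolution_on_additive_input(self, n):
        rng = np.random.default_rng(9)
        for _ in range(10):
            dm = random_additive_matrix(rng, n)
            nj_bips = nj_tree(dm).bipartitions()
            me_bips = min_evolution_tree(dm)
            assert nj_bips == me_bips

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(10)
        dm = random_additive_matrix(rng, 6)
        t1 = nj_tree(dm).bipartitions()
        perm = rng.permutation(len(dm.labels))
        labels2 = tuple(dm.labels[i] for i in perm)
        mat2 = dm.values[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(labels2, mat2)).bipartitions()
        assert t1 == t2

    def test_against_independent_nj_implementation(self):
        """Cross-check topology with scikit-bio's neighbour joining."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        dm = random_additive_matrix(rng, 6)
        ours = nj_tree(dm).bipartitions()
        sk_tree = skbio_nj(skbio.DistanceMatrix(dm.values, ids=list(dm.labels)))
        ref = min(dm.labels)
        theirs = set()
        for node in sk_tree.non_tips():
            s = frozenset(t.name for t in node.tips())
            s = s if ref not in s else frozenset(dm.labels) - s
            if 2 <= len(s) <= len(dm.labels) - 2:
                theirs.add(s)
        assert ours == theirs


class TestBootstrap:
    def test_duplicated_taxon_cherry_full_support(self):
        rng = np.random.default_rng(13)
        base = "".join(rng.choice(list("ACGT"), 300))
        other = "".join(rng.choice(list("ACGT"), 300))
        third = "".join(rng.choice(list("ACGT"), 300))
        aln = {"d1": base, "d2": base, "x": other, "y": third}
        tree = bootstrap_support(aln, reps=100, seed=1)
        assert tree.support_for(["d1", "d2"]) == 100.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(14)
        aln = ortholog_alignment(rng, n_genes=2, n_species=4, length=300)
        t1 = bootstrap_support(aln, reps=100, seed=7)
        t2 = bootstrap_support(aln, reps=100, seed=7)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_supports_bounded(self):
        rng = np.random.default_rng(15)
        aln = ortholog_alignment(rng, n_genes=2, n_species=4, length=200)
        tree = bootstrap_support(aln, reps=50, seed=3)
        assert all(0 <= v <= 100 for v in tree.supports.values())
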