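"""Neighbor joining, bootstrap support, monophyly queries, Newick output."""

import numpy as np
import pytest

from barcodeval.aligner import MarkerAlignment
from barcodeval.distances import DistanceMatrix
from barcodeval.errors import TreeError
from barcodeval.trees import Tree, bootstrap_support, nj_tree


def matrix(labels, values):
    return DistanceMatrix(labels=list(labels), values=np.array(values, float),
                          metric="p")


def random_additive_matrix(rng, n_leaves):
    """Path-length matrix of a random binary tree: the independent oracle
    for NJ recovery (NJ is consistent on additive data)."""
    import networkx as nx

    g = nx.Graph()
    g.add_edge(0, "i0", weight=rng.uniform(0.5, 2))
    g.add_edge(1, "i0", weight=rng.uniform(0.5, 2))
    g.add_edge(2, "i0", weight=rng.uniform(0.5, 2))
    edges = list(g.edges())
    for leaf in range(3, n_leaves):
        u, v = edges[rng.integers(len(edges))]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"m{leaf}"
        s = rng.uniform(0.2, 0.8)
        g.add_edge(u, mid, weight=w * s)
        g.add_edge(mid, v, weight=w * (1 - s))
        g.add_edge(leaf, mid, weight=rng.uniform(0.5, 2))
        edges = list(g.edges())
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(n_leaves):
            D[i, j] = lengths[i][j]
    D = (D + D.T) / 2.0  # exact float symmetry
    np.fill_diagonal(D, 0.0)
    bps = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nx2
        side = {x for x in nx2.node_connected_component(h, u)
                if isinstance(x, int)}
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            bps.add(frozenset(f"t{i}" for i in side))
    return D, bps


def test_three_taxon_star_closed_form():
    t = nj_tree(matrix("ABC", [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
    lengths = {}
    for u, v, w in t.edges:
        leaf = u if u < 3 else v
        lengths[t.labels[leaf]] = w
    # a = (ab+ac-bc)/2 etc.
    assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}


def test_four_taxon_additive_worked_example():
    vals = [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]]
    t = nj_tree(matrix("ABCD", vals))
    by_leaf = {}
    internal = None
    for u, v, w in t.edges:
        lo, hi = min(u, v), max(u, v)
        if lo < 4:
            by_leaf[t.labels[lo]] = w
        else:
            internal = w
    assert by_leaf == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
    assert internal == 5.0
    assert t.is_exclusive({"A", "B"})
    assert t.is_exclusive({"C", "D"})
    assert not t.is_exclusive({"A", "C"})


def test_nj_rejects_undefined_and_tiny_matrices():
    bad = matrix("ABC", [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
    with pytest.raises(TreeError):
        nj_tree(bad)
    with pytest.raises(TreeError):
        nj_tree(matrix("AB", [[0, 1], [1, 0]]))


def test_nj_recovers_random_additive_topologies():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        n = int(rng.integers(5, 11))
        D, true_bps = random_additive_matrix(rng, n)
        t = nj_tree(matrix([f"t{i}" for i in range(n)], D))
        assert set(t.bipartitions()) == true_bps


def test_nj_topology_agrees_with_independent_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(5, 9))
        D, _ = random_additive_matrix(rng, n)
        labels = [f"t{i}" for i in range(n)]
        mine = set(nj_tree(matrix(labels, D)).bipartitions())
        ref_tree = skbio_nj(skbio.DistanceMatrix(D, labels))
        ref = set()
        for node in ref_tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 2 <= len(tips) <= n - 2:
                ref.add(tips if f"t0" not in tips
                        else frozenset(labels) - tips)
        assert ref <= mine


def test_is_exclusive_trivial_cases_and_errors():
    t = nj_tree(matrix("ABC", [[0, 2, 4], [2, 0, 6], [4, 6, 0]]))
    assert t.is_exclusive({"A"})
    assert t.is_exclusive({"A", "B", "C"})
    with pytest.raises(TreeError):
        t.is_exclusive({"Z"})
    with pytest.raises(TreeError):
        t.is_exclusive(set())


def test_newick_round_trip_with_support_and_quoting():
    dendropy = pytest.importorskip("dendropy")
    labels = ["Agonum viduum", "Agonum muelleri", "Clivina fossor", "D"]
    vals = [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]]
    t = nj_tree(matrix(labels, vals))
    bp = next(iter(t.bipartitions()))
    t.support = {bp: 97.0}
    newick = t.to_newick()
    assert "'Agonum viduum'" in newick
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
    assert leaves == set(labels)
    assert "97" in newick


def _diagnostic_alignment():
    """Two 2-leaf clusters separated by 10 fixed diagnostic columns."""
    left = "A" * 10
    right = "G" * 10
    return MarkerAlignment(marker="COI", scope="global", rows=[
        ("a1", left + "C"), ("a2", left + "T"),
        ("b1", right + "C"), ("b2", right + "T"),
    ])


def test_bootstrap_diagnostic_columns_give_full_support():
    tree, skipped = bootstrap_support(_diagnostic_alignment(), "p", 100, seed=5)
    assert skipped == 0
    central = frozenset({"b1", "b2"})
    assert tree.support[central] == 100.0


def test_bootstrap_support_is_reproducible_given_seed():
    t1, _ = bootstrap_support(_diagnostic_alignment(), "p", 50, seed=9)
    t2, _ = bootstrap_support(_diagnostic_alignment(), "p", 50, seed=9)
    assert t1.support == t2.support


def test_support_range_validated():
    with pytest.raises(TreeError):
        Tree(labels=["a", "b"], edges=[(0, 1, 1.0)],
             support={frozenset({"a"}): 120.0})
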