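import math

import dendropy
import numpy as np
import pytest

from hlapopgen import (
    DistanceMatrix,
    FrequencyTable,
    PopulationFrequencySet,
    build_population_tree,
    nei_distance_matrix,
    nei_standard_distance,
    nj_tree,
)


def _pop(name, freqs, locus="B"):
    return PopulationFrequencySet(
        name=name, tables={locus: FrequencyTable(locus=locus, entries=dict(freqs))}
    )


def test_nei_distance_identical_is_zero():
    x = _pop("X", {"a": 0.5, "b": 0.5})
    y = _pop("Y", {"a": 0.5, "b": 0.5})
    assert nei_standard_distance(x, y) == 0.0


def test_nei_distance_disjoint_is_infinite():
    assert math.isinf(nei_standard_distance(_pop("X", {"a": 1.0}), _pop("Y", {"b": 1.0})))


def test_nei_distance_hand_value():
    # I = 0.5 / sqrt(0.5 * 1) = 0.7071..., D = -ln I = 0.3466
    d = nei_standard_distance(_pop("X", {"a": 0.5, "b": 0.5}), _pop("Y", {"a": 1.0}))
    assert d == pytest.approx(0.34657, abs=1e-4)


def test_nei_matrix_symmetric_zero_diagonal():
    pops = [
        _pop("P1", {"a": 0.5, "b": 0.5}),
        _pop("P2", {"a": 0.9, "b": 0.1}),
        _pop("P3", {"a": 0.2, "b": 0.7, "c": 0.1}),
    ]
    dm = nei_distance_matrix(pops)
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0)


def _path_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(
        labels=["a", "b", "c"], values=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]])
    )
    tree = nj_tree(dm)
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()}
    assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})


def _random_additive_tree(rng, n_leaves):
    """Random binary tree as a weighted graph; returns its leaf path-length
    matrix (exactly additive by construction)."""
    import networkx as nx

    g = nx.Graph()
    center = "i0"
    for k in range(3):
        g.add_edge(center, f"L{k}", weight=float(rng.uniform(0.1, 2.0)))
    next_internal = 1
    for k in range(3, n_leaves):
        u, v = list(g.edges())[rng.integers(len(g.edges()))]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, f"L{k}", weight=float(rng.uniform(0.1, 2.0)))
    leaves = [f"L{k}" for k in range(n_leaves)]
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    values = np.array([[dist[a][b] for b in leaves] for a in leaves])
    return DistanceMatrix(labels=leaves, values=values)


@pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices_exactly(n_leaves):
    rng = np.random.default_rng(100 + n_leaves)
    for _ in range(3):
        dm = _random_additive_tree(rng, n_leaves)
        tree = nj_tree(dm)
        paths = _path_lengths(tree.tree)
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert paths[frozenset((a, b))] == pytest.approx(
                    dm.values[i, j], abs=1e-9
                )


def test_nj_leafset_and_newick_reparse():
    rng = np.random.default_rng(4)
    dm = _random_additive_tree(rng, 6)
    tree = nj_tree(dm)
    assert tree.leaf_labels() == set(dm.labels)
    back = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {l.taxon.label for l in back.leaf_node_iter()} == set(dm.labels)
    # internal nodes of an unrooted NJ tree have degree 3
    for node in back.preorder_internal_node_iter():
        degree = len(node.child_nodes()) + (0 if node.parent_node is None else 1)
        assert degree == 3


def test_nj_all_equal_distances_deterministic():
    values = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(labels=["a", "b", "c", "d"], values=values)
    assert nj_tree(dm).newick() == nj_tree(dm).newick()


def test_nj_rejects_small_or_nan_input():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2))))
    values = np.ones((3, 3)) - np.eye(3)
    values[0, 1] = values[1, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        nj_tree(DistanceMatrix(labels=["a", "b", "c"], values=values))


def test_population_tree_expected_topology():
    """Nested perturbations: P1 and P2 nearly identical, P3 distant; the NJ
    tree must place P1-P2 as neighbours."""
    p1 = _pop("P1", {"a": 0.50, "b": 0.50})
    p2 = _pop("P2", {"a": 0.52, "b": 0.48})
    p3 = _pop("P3", {"a": 0.05, "b": 0.05, "c": 0.90})
    p4 = _pop("P4", {"a": 0.04, "b": 0.06, "c": 0.90})
    dm, tree = build_population_tree([p1, p2, p3, p4])
    assert dm["P1", "P2"] < dm["P1", "P3"]
    paths = _path_lengths(tree.tree)
    assert paths[frozenset(("P1", "P2"))] < paths[frozenset(("P1", "P3"))]


def test_population_tree_duplicate_population_zero_branch():
    p1 = _pop("P1", {"a": 0.5, "b": 0.5})
    p1b = _pop("P1copy", {"a": 0.5, "b": 0.5})
    p3 = _pop("P3", {"a": 0.1, "b": 0.9})
    dm, tree = build_population_tree([p1, p1b, p3])
    assert dm["P1", "P1copy"] == 0.0
    lengths = {l.taxon.label: l.edge.length for l in tree.tree.leaf_node_iter()}
    assert lengths["P1"] == pytest.approx(0.0, abs=1e-12)


def test_population_tree_infinite_distance_errors():
    pops = [_pop("X", {"a": 1.0}), _pop("Y", {"b": 1.0}), _pop("Z", {"a": 0.5, "b": 0.5})]
    with pytest.raises(ValueError, match="infinite"):
        build_population_tree(pops)


def test_many_random_populations_smoke():
    rng = np.random.default_rng(0)
    pops = []
    for k in range(24):
        f = rng.dirichlet(np.ones(51) * 0.3)
        pops.append(_pop(f"Pop{k:02d}", {f"{i:04d}": float(x) for i, x in enumerate(f)}))
    dm, tree = build_population_tree(pops)
    assert len(tree.leaf_labels()) == 24
    dendropy.Tree.get(data=tree.newick(), schema="newick")
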