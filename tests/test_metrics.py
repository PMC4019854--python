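"""The seven network metrics against brute-force and networkx oracles."""

import networkx as nx
import numpy as np
import pytest

import _oracles as oracle
from connrepro import (
    DegenerateGraphError,
    all_pairs_shortest_path_lengths,
    assortativity,
    characteristic_path_length,
    compute_density,
    global_efficiency,
    largest_component_size,
    local_efficiency,
    mean_clustering_coefficient,
    rich_club_coefficient,
)
from conftest import graph_from_edges, random_adjacency

from connrepro import BinaryGraph

TOL = 1e-12


def complete_graph(n):
    return graph_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


P3 = graph_from_edges(3, [(0, 1), (1, 2)])


class TestShortestPaths:
    def test_path_graph_hop_counts(self):
        lengths = all_pairs_shortest_path_lengths(P3)
        assert lengths[0, 2] == 2
        assert lengths[0, 0] == 0

    def test_disconnected_pairs_are_infinite(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        lengths = all_pairs_shortest_path_lengths(g)
        assert np.isinf(lengths[0, 2])

    def test_complete_graph_all_ones(self):
        lengths = all_pairs_shortest_path_lengths(complete_graph(5))
        off = ~np.eye(5, dtype=bool)
        assert np.all(lengths[off] == 1)


class TestClosedForms:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_gives_one_everywhere(self, n):
        g = complete_graph(n)
        assert mean_clustering_coefficient(g) == pytest.approx(1.0, abs=TOL)
        assert characteristic_path_length(g) == pytest.approx(1.0, abs=TOL)
        assert global_efficiency(g) == pytest.approx(1.0, abs=TOL)
        assert local_efficiency(g) == pytest.approx(1.0, abs=TOL)

    def test_path_graph_hand_values(self):
        assert mean_clustering_coefficient(P3) == 0.0
        assert characteristic_path_length(P3) == pytest.approx(4 / 3, abs=TOL)
        assert global_efficiency(P3) == pytest.approx(5 / 6, abs=TOL)
        assert local_efficiency(P3) == 0.0

    def test_star_is_perfectly_disassortative(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert assortativity(star) == pytest.approx(-1.0, abs=TOL)

    def test_regular_graph_assortativity_undefined(self):
        assert assortativity(complete_graph(4)) is None

    def test_cpl_uses_largest_component_only(self):
        tri_plus_isolate = graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        assert characteristic_path_length(tri_plus_isolate) == pytest.approx(1.0)

    def test_largest_component_size_cases(self):
        assert largest_component_size(graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])) == 3
        assert largest_component_size(graph_from_edges(4, [])) == 1

    def test_rich_club_cases(self):
        g = complete_graph(4)
        assert rich_club_coefficient(g, 3) == pytest.approx(1.0)
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert rich_club_coefficient(star, 2) is None

    def test_edgeless_graph_behavior(self):
        empty = graph_from_edges(4, [])
        assert global_efficiency(empty) == 0.0
        with pytest.raises(DegenerateGraphError):
            characteristic_path_length(empty)
        with pytest.raises(DegenerateGraphError):
            assortativity(empty)


@pytest.mark.parametrize("seed", range(40))
def test_all_metrics_match_brute_force_oracles(seed):
    """Exhaustive-implementation equivalence on small random graphs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    adj = random_adjacency(rng, n, float(rng.uniform(0.2, 0.8)))
    g = BinaryGraph(adjacency=adj)
    a = adj.astype(int)
    assert mean_clustering_coefficient(g) == pytest.approx(oracle.clustering(a), abs=TOL)
    assert global_efficiency(g) == pytest.approx(oracle.global_efficiency(a), abs=TOL)
    assert local_efficiency(g) == pytest.approx(oracle.local_efficiency(a), abs=TOL)
    assert largest_component_size(g) == oracle.largest_component_size(a)
    if a.sum() > 0:
        assert characteristic_path_length(g) == pytest.approx(
            oracle.characteristic_path_length(a), abs=TOL
        )
        ours, ref = assortativity(g), oracle.assortativity(a)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=TOL)
    for k in range(0, int(a.sum(axis=1).max()) + 2):
        ours, ref = rich_club_coefficient(g, k), oracle.rich_club(a, k)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=TOL)


@pytest.mark.parametrize("seed", range(10))
def test_metrics_agree_with_networkx(seed):
    """Cross-check against an unrelated third-party implementation."""
    rng = np.random.default_rng(seed + 1000)
    n = 12
    adj = random_adjacency(rng, n, 0.4)
    g = BinaryGraph(adjacency=adj)
    G = nx.from_numpy_array(adj)
    assert mean_clustering_coefficient(g) == pytest.approx(
        nx.average_clustering(G), abs=1e-9
    )
    assert global_efficiency(g) == pytest.approx(nx.global_efficiency(G), abs=1e-9)
    assert local_efficiency(g) == pytest.approx(nx.local_efficiency(G), abs=1e-9)
    ours = assortativity(g)
    if ours is not None:
        assert ours == pytest.approx(
            nx.degree_assortativity_coefficient(G), abs=1e-9
        )


@pytest.mark.parametrize("seed", range(5))
def test_metrics_invariant_under_node_relabeling(seed):
    rng = np.random.default_rng(seed + 77)
    adj = random_adjacency(rng, 10, 0.5)
    perm = rng.permutation(10)
    permuted = adj[np.ix_(perm, perm)]
    g, h = BinaryGraph(adjacency=adj), BinaryGraph(adjacency=permuted)
    for fn in (
        mean_clustering_coefficient,
        characteristic_path_length,
        global_efficiency,
        local_efficiency,
    ):
        assert fn(g) == pytest.approx(fn(h), abs=TOL)
    assert largest_component_size(g) == largest_component_size(h)


def test_rich_club_at_zero_equals_density(rng):
    for _ in range(20):
        adj = random_adjacency(rng, 9, float(rng.uniform(0.2, 0.9)))
        g = BinaryGraph(adjacency=adj)
        assert rich_club_coefficient(g, 0) == pytest.approx(
            compute_density(g), abs=TOL
        )


def test_adding_edge_never_hurts_efficiency_or_cpl(rng):
    """Global efficiency is monotone in edges; CPL on a fixed connected
    node set never increases when an edge is added."""
    for _ in range(10):
        adj = random_adjacency(rng, 8, 0.5)
        g = BinaryGraph(adjacency=adj)
        absent = [
            (i, j)
            for i in range(8)
            for j in range(i + 1, 8)
            if not adj[i, j]
        ]
        if not absent:
            continue
        i, j = absent[int(rng.integers(len(absent)))]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        h = BinaryGraph(adjacency=adj2)
        assert global_efficiency(h) >= global_efficiency(g) - TOL
        if largest_component_size(g) == 8:
            assert characteristic_path_length(h) <= characteristic_path_length(g) + TOL
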