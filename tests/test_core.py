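"""Graph data model: validation, density, thresholding, components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from connrepro import (
    BinaryGraph,
    ConnectivityMatrix,
    DegenerateGraphError,
    InfeasibleDensityError,
    MatrixValidationError,
    compute_density,
    connected_components,
    degrees,
    largest_connected_component,
    max_density,
    threshold_to_density,
    validate_matrix,
)
from conftest import graph_from_edges, matrix_from_weights, random_weights


class TestValidateMatrix:
    def test_valid_matrix_returned_unchanged(self):
        w = np.array([[0, 2, 1], [2, 0, 3], [1, 3, 0]], float)
        m = matrix_from_weights(w)
        assert validate_matrix(m) is m

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda w: w.__setitem__((0, 1), 99), "asymmetric"),
            (lambda w: w.__setitem__((1, 1), 5.0), "diagonal"),
            (
                lambda w: (w.__setitem__((0, 2), -1), w.__setitem__((2, 0), -1)),
                "negative",
            ),
        ],
    )
    def test_violated_invariants_raise_distinct_messages(self, mutate, message):
        w = np.array([[0, 2, 1], [2, 0, 3], [1, 3, 0]], float)
        mutate(w)
        with pytest.raises(MatrixValidationError, match=message):
            validate_matrix(matrix_from_weights(w))

    def test_too_few_nodes(self):
        with pytest.raises(MatrixValidationError, match="2 nodes"):
            validate_matrix(matrix_from_weights(np.zeros((1, 1))))


class TestDensity:
    @pytest.mark.parametrize(
        "n, edges, expected",
        [
            (4, [(0, 1), (1, 2), (2, 3), (3, 0)], 2 / 3),  # 4-cycle
            (5, [(i, j) for i in range(5) for j in range(i + 1, 5)], 1.0),
            (6, [], 0.0),
        ],
    )
    def test_closed_forms(self, n, edges, expected):
        g = graph_from_edges(n, edges)
        assert compute_density(g) == pytest.approx(expected, abs=1e-15)

    def test_max_density_counts_positive_edges(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 5
        w[1, 2] = w[2, 1] = 2
        assert max_density(matrix_from_weights(w)) == pytest.approx(2 / 3)
        assert max_density(matrix_from_weights(np.zeros((4, 4)))) == 0.0
        full = random_weights(np.random.default_rng(0), 5, p=1.0)
        assert max_density(matrix_from_weights(full)) == 1.0


class TestThresholding:
    def test_top_weighted_edges_selected(self):
        w = np.zeros((4, 4))
        for (i, j), v in zip(
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], [10, 8, 6, 4, 2, 1]
        ):
            w[i, j] = w[j, i] = v
        g = threshold_to_density(matrix_from_weights(w), 0.5)
        expected = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert np.array_equal(g.adjacency, expected.adjacency)
        assert g.density == pytest.approx(0.5)

    def test_full_density_keeps_all_positive_edges(self, rng):
        w = random_weights(rng, 8)
        m = matrix_from_weights(w)
        g = threshold_to_density(m, max_density(m))
        assert np.array_equal(g.adjacency > 0, w > 0)

    def test_tie_break_prefers_lowest_index_pair(self):
        w = np.zeros((3, 3))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            w[i, j] = w[j, i] = 5
        g = threshold_to_density(matrix_from_weights(w), 1 / 3)
        assert np.array_equal(
            g.adjacency, graph_from_edges(3, [(0, 1)]).adjacency
        )

    def test_infeasible_density_names_achievable_maximum(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1
        with pytest.raises(InfeasibleDensityError, match="0.33"):
            threshold_to_density(matrix_from_weights(w), 0.9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_with_exact_edge_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        w = random_weights(rng, n, p=0.7)
        m = matrix_from_weights(w)
        d = float(rng.uniform(0.05, max_density(m)))
        g = threshold_to_density(m, d)
        n_expected = int(np.floor(d * n * (n - 1) / 2 + 0.5))
        got = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if g.adjacency[i, j]
        }
        assert len(got) == n_expected
        assert got == oracle.top_edges_by_weight(w, n_expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_nested_edge_sets_across_densities(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weights(rng, 9, p=0.8)
        m = matrix_from_weights(w)
        top = max_density(m)
        densities = np.linspace(0.05, top, 5)
        prev = None
        for d in densities:
            g = threshold_to_density(m, float(d))
            if prev is not None:
                assert np.all(prev.adjacency <= g.adjacency)
            prev = g

    def test_deterministic_under_ties(self, rng):
        w = (random_weights(rng, 10, p=0.9) > 0).astype(float) * 7  # all ties
        m = matrix_from_weights(w)
        g1 = threshold_to_density(m, 0.2)
        g2 = threshold_to_density(m, 0.2)
        assert np.array_equal(g1.adjacency, g2.adjacency)


class TestComponents:
    def test_partition_of_two_triangles(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        blocks = connected_components(g)
        assert [sorted(b) for b in blocks] == [[0, 1, 2], [3, 4, 5]]

    def test_partition_is_disjoint_cover(self, rng):
        from conftest import random_adjacency

        for _ in range(20):
            adj = random_adjacency(rng, 12, 0.15)
            blocks = connected_components(BinaryGraph(adjacency=adj))
            flat = np.sort(np.concatenate(blocks))
            assert np.array_equal(flat, np.arange(12))

    def test_lcc_picks_biggest_then_lowest_index(self):
        tri_plus_edge = graph_from_edges(5, [(0, 1), (1, 2), (0, 2), (3, 4)])
        assert largest_connected_component(tri_plus_edge).n_nodes == 3
        two_edges = graph_from_edges(4, [(0, 1), (2, 3)])
        lcc = largest_connected_component(two_edges)
        assert lcc.node_labels == ["region_0001", "region_0002"]

    def test_lcc_of_edgeless_graph_errors(self):
        with pytest.raises(DegenerateGraphError):
            largest_connected_component(graph_from_edges(4, []))


def test_degrees_are_row_sums():
    star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
    assert degrees(star).tolist() == [3, 1, 1, 1]
    assert degrees(graph_from_edges(3, [])).tolist() == [0, 0, 0]
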