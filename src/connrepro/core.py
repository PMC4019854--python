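"""Graph data model: connectivity matrices, density thresholding, components.

A connectivity matrix records how many tractography streamlines join each
pair of brain regions.  Graphs are compared at constant density: the
top-weighted edges are kept until the requested edge count is reached, then
binarized (cumulative thresholding).  Density of an undirected graph is
taken as ``2E / (N(N-1))`` so it spans [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph


class MatrixValidationError(ValueError):
    """A connectivity matrix violates a structural invariant."""


class InfeasibleDensityError(ValueError):
    """Requested density exceeds the matrix's maximal (all-positive-edge) density."""


class DegenerateGraphError(ValueError):
    """Operation undefined on this graph (typically: no edges)."""


def default_node_labels(n: int) -> list[str]:
    return [f"region_{i + 1:04d}" for i in range(n)]


@dataclass
class ConnectivityMatrix:
    """Weighted symmetric streamline-count matrix with cohort identity.

    ``weights[i, j]`` is the number of streamlines connecting regions i and j
    (nonnegative, zero diagonal, symmetric — tractography is undirected).
    """

    weights: np.ndarray
    node_labels: list[str] | None = None
    subject_id: str = ""
    session_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise MatrixValidationError(
                f"weights must be a square matrix, got shape {self.weights.shape}"
            )
        if self.node_labels is None:
            self.node_labels = default_node_labels(self.weights.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryGraph:
    """Thresholded, binarized adjacency with its realized density."""

    adjacency: np.ndarray
    node_labels: list[str] | None = None
    density: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.dtype != np.int8:
            self.adjacency = (self.adjacency != 0).astype(np.int8)
        if self.node_labels is None:
            self.node_labels = default_node_labels(self.adjacency.shape[0])
        if self.density is None:
            self.density = compute_density(self)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def validate_matrix(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Check all ConnectivityMatrix invariants; return the matrix unchanged.

    Raises :class:`MatrixValidationError` with a distinct message per
    violated invariant (asymmetry, negative entry, nonzero diagonal, N < 2).
    """
    w = m.weights
    if w.shape[0] < 2:
        raise MatrixValidationError(f"matrix must have at least 2 nodes, got {w.shape[0]}")
    if not np.array_equal(w, w.T):
        raise MatrixValidationError("matrix is asymmetric: weights[i, j] != weights[j, i]")
    if np.any(w < 0):
        raise MatrixValidationError("matrix contains negative entries")
    if np.any(np.diagonal(w) != 0):
        raise MatrixValidationError(
            "matrix has nonzero diagonal entries (self-connections are not allowed)"
        )
    if m.node_labels is not None and len(m.node_labels) != w.shape[0]:
        raise MatrixValidationError(
            f"{len(m.node_labels)} node labels for {w.shape[0]} nodes"
        )
    return m


def compute_density(g: BinaryGraph) -> float:
    """Density 2E / (N(N-1)) of a binary undirected graph."""
    n = g.adjacency.shape[0]
    return float(g.adjacency.sum()) / (n * (n - 1))


def max_density(m: ConnectivityMatrix) -> float:
    """Density of the graph keeping every strictly positive edge of ``m``."""
    n = m.n_nodes
    iu = np.triu_indices(n, k=1)
    n_pos = int(np.count_nonzero(m.weights[iu] > 0))
    return 2.0 * n_pos / (n * (n - 1))


def edge_count_for_density(target_density: float, n_nodes: int) -> int:
    """Edge count for a density target: round-half-up of d * N(N-1)/2."""
    pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(target_density * pairs + 0.5))


def threshold_to_density(m: ConnectivityMatrix, target_density: float) -> BinaryGraph:
    """Binarize ``m`` by cumulative density thresholding.

    Keeps exactly ``round_half_up(d * N(N-1)/2)`` edges, chosen by the total
    order (weight descending, then (i, j) index pair ascending); surviving
    weights become 1.  The fixed order makes thresholding deterministic under
    ties and the edge sets nested across increasing densities.
    """
    if not 0.0 <= target_density <= 1.0:
        raise InfeasibleDensityError(
            f"target density must lie in [0, 1], got {target_density}"
        )
    n = m.n_nodes
    rows, cols = np.triu_indices(n, k=1)
    w = m.weights[rows, cols]
    n_edges = edge_count_for_density(target_density, n)
    positive = w > 0
    n_pos = int(np.count_nonzero(positive))
    if n_edges > n_pos:
        raise InfeasibleDensityError(
            f"target density {target_density} needs {n_edges} edges but only "
            f"{n_pos} positive edges exist; achievable maximum density is "
            f"{2.0 * n_pos / (n * (n - 1)):.6g}"
        )
    # lexsort: last key is primary -> weight desc, then row asc, then col asc
    order = np.lexsort((cols, rows, -w))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[rows[keep], cols[keep]] = 1
    adj[cols[keep], rows[keep]] = 1
    return BinaryGraph(adjacency=adj, node_labels=list(m.node_labels))


def connected_components(g: BinaryGraph) -> list[np.ndarray]:
    """Partition of node indices into maximal connected blocks.

    Blocks are returned ordered by their smallest contained node index;
    together they cover all nodes and are pairwise disjoint.
    """
    n_comp, labels = csgraph.connected_components(
        csr_matrix(g.adjacency), directed=False
    )
    blocks = [np.flatnonzero(labels == c) for c in range(n_comp)]
    blocks.sort(key=lambda b: int(b[0]))
    return blocks


def largest_connected_component(g: BinaryGraph) -> BinaryGraph:
    """Induced subgraph on the component with the most nodes.

    Ties are broken toward the component containing the smallest node index.
    Raises :class:`DegenerateGraphError` on an edgeless graph.
    """
    if g.n_edges == 0:
        raise DegenerateGraphError("largest connected component of an edgeless graph")
    blocks = connected_components(g)
    best = max(blocks, key=lambda b: (len(b), -int(b[0])))
    sub = g.adjacency[np.ix_(best, best)]
    labels = [g.node_labels[i] for i in best]
    return BinaryGraph(adjacency=sub, node_labels=labels)


def degrees(g: BinaryGraph) -> np.ndarray:
    """Degree of each node (row sums of the adjacency matrix)."""
    return g.adjacency.sum(axis=1).astype(np.int64)
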