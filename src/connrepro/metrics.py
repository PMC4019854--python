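"""Binary undirected network summary measures.

Seven whole-network metrics for thresholded connectomes: mean clustering
coefficient, characteristic path length (on the largest connected
component), largest-component size, degree assortativity, global and local
efficiency, and the rich-club coefficient.  All operate on unweighted,
undirected graphs; metrics that can be undefined (assortativity with a
degenerate denominator, rich club with fewer than two qualifying nodes)
return ``None`` rather than NaN so downstream curve code records the gap
explicitly.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from .core import (
    BinaryGraph,
    DegenerateGraphError,
    degrees,
    largest_connected_component,
)


def all_pairs_shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """Hop-count distance matrix (breadth-first search from every node).

    ``L[i, j]`` is the minimum number of edges on a path from i to j, with
    ``inf`` for pairs in different components and 0 on the diagonal.
    """
    return csgraph.shortest_path(
        csr_matrix(g.adjacency), method="D", unweighted=True, directed=False
    )


def mean_clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over nodes of C_i = 2 e_i / (k_i (k_i - 1)).

    e_i counts edges among the neighbors of node i.  Nodes of degree < 2
    have a vanishing denominator and contribute C_i = 0.
    """
    a = g.adjacency.astype(float)
    k = degrees(g)
    # (A^3)_ii counts ordered closed triples = 2 * edges among neighbors
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 e_i per node
    denom = k * (k - 1)
    c = np.zeros(g.n_nodes)
    ok = denom > 0
    c[ok] = tri2[ok] / denom[ok]
    return float(c.mean())


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over node pairs of the largest component.

    Path length is only defined within a connected graph, so the largest
    connected component is extracted first.  Raises
    :class:`DegenerateGraphError` on an edgeless graph.
    """
    lcc = largest_connected_component(g)
    lengths = all_pairs_shortest_path_lengths(lcc)
    n = lcc.n_nodes
    off = ~np.eye(n, dtype=bool)
    return float(lengths[off].mean())


def largest_component_size(g: BinaryGraph) -> int:
    """Node count of the largest connected component (1 for edgeless graphs)."""
    _, labels = csgraph.connected_components(csr_matrix(g.adjacency), directed=False)
    return int(np.bincount(labels).max())


def largest_component_fraction(g: BinaryGraph) -> float:
    """Largest-component size as a fraction of all nodes."""
    return largest_component_size(g) / g.n_nodes


def assortativity(g: BinaryGraph) -> Optional[float]:
    """Degree assortativity: correlation of end-point degrees over edges.

    With (j_i, k_i) the degrees of the two endpoints of edge i and E the
    number of undirected edges:

        A = [ <j k> - <(j + k)/2>^2 ] / [ <(j^2 + k^2)/2> - <(j + k)/2>^2 ]

    where <.> averages over edges.  Returns ``None`` when the denominator is
    zero (all edge endpoints have identical degree).  Raises
    :class:`DegenerateGraphError` on an edgeless graph.
    """
    rows, cols = np.triu_indices(g.n_nodes, k=1)
    present = g.adjacency[rows, cols] != 0
    if not present.any():
        raise DegenerateGraphError("assortativity of an edgeless graph")
    deg = degrees(g).astype(float)
    j = deg[rows[present]]
    k = deg[cols[present]]
    mean_prod = (j * k).mean()
    mean_sum = (0.5 * (j + k)).mean()
    mean_sq = (0.5 * (j**2 + k**2)).mean()
    denom = mean_sq - mean_sum**2
    if denom == 0.0:
        return None
    return float((mean_prod - mean_sum**2) / denom)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over all ordered node pairs.

    Disconnected pairs contribute 0 (1/inf); no component extraction, so
    the measure is defined for unconnected graphs.
    """
    n = g.n_nodes
    if n < 2:
        raise DegenerateGraphError("global efficiency needs at least 2 nodes")
    lengths = all_pairs_shortest_path_lengths(g)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / lengths[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    For node i the subgraph induced on i's neighbors measures how
    efficiently they communicate were i removed; nodes with fewer than two
    neighbors contribute 0.
    """
    total = 0.0
    adj = g.adjacency
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = BinaryGraph(adjacency=adj[np.ix_(nbrs, nbrs)])
        total += global_efficiency(sub)
    return total / g.n_nodes


def rich_club_coefficient(g: BinaryGraph, k: int) -> Optional[float]:
    """Density of the subgraph induced on nodes of degree >= k.

    R(G, k) = 2 ||E(G, k)|| / (||N(G, k)|| (||N(G, k)|| - 1)), with degree
    measured in the full graph.  Returns ``None`` when fewer than two nodes
    qualify.  R(G, 0) equals the density of G.
    """
    deg = degrees(g)
    members = np.flatnonzero(deg >= k)
    n_k = members.size
    if n_k < 2:
        return None
    e_k = int(g.adjacency[np.ix_(members, members)].sum()) // 2
    return 2.0 * e_k / (n_k * (n_k - 1))


#: Metrics evaluated along the graph-density sweep (rich club is swept over
#: the degree threshold k at fixed density instead; see ``curves``).
DENSITY_METRICS: dict[str, Callable[[BinaryGraph], Optional[float]]] = {
    "clustering": mean_clustering_coefficient,
    "char_path_length": characteristic_path_length,
    "largest_component_size": lambda g: float(largest_component_size(g)),
    "assortativity": assortativity,
    "global_efficiency": global_efficiency,
    "local_efficiency": local_efficiency,
}

METRIC_NAMES = tuple(DENSITY_METRICS) + ("rich_club",)
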