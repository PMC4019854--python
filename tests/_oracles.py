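"""Independent brute-force implementations used as oracles in tests.

Everything here is deliberately naive — explicit loops, Floyd-Warshall,
direct formula evaluation — and shares no code with the package beyond the
adjacency-matrix convention, so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), INF)
    for i in range(n):
        dist[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def components(adj: np.ndarray) -> list[set[int]]:
    n = adj.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in range(n) if adj[u, v] and v not in comp)
        comps.append(comp)
        seen |= comp
    return comps


def largest_component(adj: np.ndarray) -> set[int]:
    comps = components(adj)
    best_size = max(len(c) for c in comps)
    return min((c for c in comps if len(c) == best_size), key=min)


def largest_component_size(adj: np.ndarray) -> int:
    return len(largest_component(adj))


def clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        total += 2.0 * e / (k * (k - 1))
    return total / n


def characteristic_path_length(adj: np.ndarray) -> float:
    comp = sorted(largest_component(adj))
    sub = adj[np.ix_(comp, comp)]
    dist = floyd_warshall(sub)
    n = len(comp)
    return sum(
        dist[i, j] for i in range(n) for j in range(n) if i != j
    ) / (n * (n - 1))


def assortativity(adj: np.ndarray):
    n = adj.shape[0]
    deg = [int(adj[i].sum()) for i in range(n)]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    e = len(edges)
    if e == 0:
        return None
    s_jk = sum(deg[i] * deg[j] for i, j in edges) / e
    s_half = sum(0.5 * (deg[i] + deg[j]) for i, j in edges) / e
    s_sq = sum(0.5 * (deg[i] ** 2 + deg[j] ** 2) for i, j in edges) / e
    denom = s_sq - s_half**2
    if denom == 0:
        return None
    return (s_jk - s_half**2) / denom


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    total = sum(
        (1.0 / dist[i, j] if dist[i, j] < INF else 0.0)
        for i in range(n)
        for j in range(n)
        if i != j
    )
    return total / (n * (n - 1))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        total += global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def rich_club(adj: np.ndarray, k: int):
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    members = [i for i in range(n) if deg[i] >= k]
    if len(members) < 2:
        return None
    e = sum(
        1 for a, b in itertools.combinations(members, 2) if adj[a, b]
    )
    return 2.0 * e / (len(members) * (len(members) - 1))


def density(adj: np.ndarray) -> float:
    n = adj.shape[0]
    e = int(adj.sum()) // 2
    return 2.0 * e / (n * (n - 1))


def top_edges_by_weight(weights: np.ndarray, n_edges: int) -> set[tuple[int, int]]:
    """Thresholding oracle: sort pairs by (-w, i, j), take the first n_edges."""
    n = weights.shape[0]
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i, j] > 0
    ]
    pairs.sort(key=lambda p: (-weights[p[0], p[1]], p[0], p[1]))
    return set(pairs[:n_edges])
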