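"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the textbook definitions with no calls
into the package or into networkx's analysis algorithms, so agreement is
meaningful: BFS by hand, explicit shortest-path enumeration, dense
eigendecomposition, exhaustive partition search for modularity, and
iterative peeling for k-cores.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def graph_adj(edges, nodes=()) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def all_shortest_paths(adj, s, t):
    """Every geodesic from s to t, via predecessor-DAG backtracking."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    preds: dict[str, list[str]] = {s: []}
    order = sorted(dist, key=dist.get)
    for v in order:
        if v == s:
            continue
        preds[v] = [u for u in adj[v] if u in dist and dist[u] == dist[v] - 1]

    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s, *reversed(acc)])
            return
        for u in preds[v]:
            back(u, acc + [v])

    back(t, [])
    return paths


def brute_betweenness(adj, normalized=False) -> dict[str, float]:
    """Sum over pairs of the fraction of geodesics through each node,
    endpoints excluded; optional per-component normalization."""
    out = {n: 0.0 for n in adj}
    comps = connected_components(adj)
    for comp in comps:
        comp = sorted(comp)
        for j, k in itertools.combinations(comp, 2):
            paths = all_shortest_paths(adj, j, k)
            if not paths:
                continue
            g_jk = len(paths)
            counts: dict[str, int] = {}
            for p in paths:
                for v in p[1:-1]:
                    counts[v] = counts.get(v, 0) + 1
            for v, c in counts.items():
                out[v] += c / g_jk
        if normalized:
            n = len(comp)
            denom = (n - 1) * (n - 2) / 2
            if denom > 0:
                for v in comp:
                    out[v] /= denom
            else:
                for v in comp:
                    out[v] = 0.0
    return out


def brute_closeness(adj) -> dict[str, float]:
    """n / sum of geodesic distances over the n other nodes of the
    component; isolated nodes score 0."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        others = {u: d for u, d in dist.items() if u != v}
        out[v] = len(others) / sum(others.values()) if others else 0.0
    return out


def brute_clustering(adj) -> dict[str, float]:
    """2 * (edges among neighbours) / (k (k - 1)); 0 for degree < 2."""
    out = {}
    for v in adj:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        m = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * m / (k * (k - 1))
    return out


def dense_principal_eigenvector(adj) -> dict[str, float]:
    """Unit-L2 principal eigenvector of the largest component's adjacency
    matrix via numpy eigendecomposition; zeros elsewhere."""
    comps = connected_components(adj)
    comps.sort(key=lambda c: (-len(c), min(c)))
    comp = sorted(comps[0])
    idx = {n: i for i, n in enumerate(comp)}
    a = np.zeros((len(comp), len(comp)))
    for u in comp:
        for v in adj[u]:
            if v in idx:
                a[idx[u], idx[v]] = 1.0
    w, vecs = np.linalg.eigh(a)
    vec = vecs[:, np.argmax(w)]
    vec = np.abs(vec) / np.linalg.norm(vec)
    out = {n: 0.0 for n in adj}
    for n in comp:
        out[n] = float(vec[idx[n]])
    return out


def connected_components(adj) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def modularity_of(adj, partition, m) -> float:
    """Newman-Girvan Q = sum_c (e_c / m - (d_c / 2m)^2)."""
    q = 0.0
    for comm in partition:
        comm = set(comm)
        e_c = sum(1 for u in comm for v in adj[u] if v in comm and u < v)
        d_c = sum(len(adj[u]) for u in comm)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first, *smaller[i]]] + smaller[i + 1:]
        yield [[first], *smaller]


def max_modularity(adj) -> float:
    """Exact maximum modularity over every partition (graphs <= ~9 nodes)."""
    m = sum(len(v) for v in adj.values()) // 2
    best = -1.0
    for part in set_partitions(sorted(adj)):
        best = max(best, modularity_of(adj, part, m))
    return best


def has_k_core(adj, k: int) -> bool:
    """Iterative peeling: does a subgraph with min degree >= k survive?"""
    alive = {n: set(nbrs) for n, nbrs in adj.items()}
    changed = True
    while changed:
        changed = False
        for n in list(alive):
            if len(alive[n]) < k:
                for v in alive[n]:
                    alive[v].discard(n)
                del alive[n]
                changed = True
    return bool(alive)


def mean_discrete_powerlaw(alpha: float, xmin: int, cap: int = 200000) -> float:
    """E[X] for the discrete power law by direct pmf summation."""
    xs = np.arange(xmin, cap, dtype=float)
    w = xs ** (-alpha)
    return float(np.sum(xs * w) / np.sum(w))
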