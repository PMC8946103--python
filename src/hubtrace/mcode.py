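"""MCODE molecular-complex detection (Bader & Hogue seed-and-grow).

Vertex weighting scores each node by the density of its closed
neighbourhood's densest k-core; complexes grow outward from the
highest-weight unvisited seed, including neighbours whose weight stays
within ``node_score_cutoff`` of the seed's; post-processing discards
complexes without a 2-core (parameter ``k_core``) and, with ``haircut``,
iteratively trims members with fewer than two intra-complex connections.
The complex score is density x size.  Complexes are node-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from hubtrace.netio import Network, NodeAnnotations


@dataclass(frozen=True)
class McodeParams:
    """MCODE parameters; defaults follow the stringent setting commonly
    used for PPI complex filtering (haircut on, fluff off)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    max_depth: int = 100

    def __post_init__(self):
        if not 0 <= self.node_score_cutoff < 1:
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class McodeCluster:
    members: frozenset[str]
    seed: str
    density: float
    score: float
    rank: int

    def __post_init__(self):
        if not 0 <= self.density <= 1:
            raise ValueError("density must lie in [0, 1]")


def _graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The densest (maximum-k) k-core of g and its k."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_num = nx.core_number(g)
    kmax = max(core_num.values())
    core = g.subgraph([n for n, c in core_num.items() if c >= kmax])
    return kmax, core


def mcode_vertex_weights(net: Network, params: McodeParams = McodeParams()) -> "NodeMeasure":
    """Per-node MCODE weight: (highest k-core number of the closed
    neighbourhood) x (density of that core); 0 below the degree cutoff."""
    from hubtrace.topology import NodeMeasure

    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.graph
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        kmax, core = _highest_kcore(closed)
        weights[v] = kmax * _graph_density(core)
    return NodeMeasure(name="mcode_weight", values=weights)


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with < 2 connections inside the complex
    (fixpoint; idempotent)."""
    members = set(members)
    while True:
        sub = g.subgraph(members)
        drop = {n for n in members if sub.degree(n) < 2}
        if not drop:
            return members
        members -= drop


def mcode_find_complexes(
    net: Network, params: McodeParams = McodeParams()
) -> list[McodeCluster]:
    """Predict node-disjoint dense complexes, ranked by score descending
    (ties broken by seed id)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.graph
    weights = mcode_vertex_weights(net, params).values
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []

    # seeds in decreasing weight, lexicographic id on ties
    for seed in sorted(g.nodes, key=lambda n: (-weights[n], n)):
        if seed in visited or g.degree(seed) < params.degree_cutoff:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        for _ in range(params.max_depth):
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        raw.append((seed, members))

    clusters: list[McodeCluster] = []
    for seed, members in raw:
        sub = g.subgraph(members)
        kmax, _ = _highest_kcore(sub)
        if kmax < params.k_core:
            continue
        if params.haircut:
            members = _haircut(g, members)
            if not members:
                continue
        sub = g.subgraph(members)
        density = _graph_density(sub)
        clusters.append(McodeCluster(
            members=frozenset(members), seed=seed, density=density,
            score=density * len(members), rank=0,
        ))
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return [McodeCluster(members=c.members, seed=c.seed, density=c.density,
                         score=c.score, rank=i + 1)
            for i, c in enumerate(clusters)]


def filter_drug_genes(
    clusters: list[McodeCluster],
    ann: NodeAnnotations,
    min_score: float = 10.0,
) -> set[str]:
    """Drug-associated genes that are members of any complex whose score
    reaches ``min_score`` (monotone: raising min_score never adds genes)."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    out: set[str] = set()
    for cluster in clusters:
        if cluster.score >= min_score:
            out |= {g for g in cluster.members
                    if ann.is_drug_associated(g) is True}
    return out


def clusters_to_tsv(clusters: list[McodeCluster], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("rank\tscore\tdensity\tsize\tseed\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.rank}\t{c.score:.6g}\t{c.density:.6g}\t{len(c.members)}"
                f"\t{c.seed}\t{','.join(sorted(c.members))}\n"
            )
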