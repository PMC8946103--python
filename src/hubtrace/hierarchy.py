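"""Iterative Louvain decomposition, hub tracing and key-regulator calls.

The network is recursively partitioned by Louvain modularity maximisation:
every community that still contains a hub (a node whose *root* degree
reaches the hub threshold) is split again, down to triangle motifs
G(3,3).  A hub whose community trace terminates inside a motif is
"motif-localized"; the motif-localized hubs whose motifs lie at the
deepest motif level of the tree are the network's key regulators (KRs).

Per-level regulating strength of a gene is summarised by
P_KR(s) = x[s] / N[s]: the fraction of the level-s community's edges
incident to the gene.  Level numbering: the whole network is level 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from hubtrace.netio import Network, induced_subgraph

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42


@dataclass
class CommunityNode:
    """A community in the nested decomposition.

    ``id`` is a path-like identifier ("0", "0.2", "0.2.1", ...); ``level``
    counts splits from the root (root = 0); ``edge_count`` is the edge
    count of the community's induced subgraph (N[s] of the P_KR
    formula); ``q_of_split`` is the modularity of the Louvain partition
    applied to this community (None for leaves).
    """

    id: str
    level: int
    members: frozenset[str]
    edge_count: int
    q_of_split: float | None = None
    children: list["CommunityNode"] = field(default_factory=list)

    @property
    def is_motif(self) -> bool:
        """A triangle motif G(3,3): exactly 3 nodes and 3 edges."""
        return len(self.members) == 3 and self.edge_count == 3

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class HubTrace:
    """The community path of one hub from the root to its deepest
    community, with its intra-community degree x[s] at every level."""

    gene: str
    degree_in_root: int
    path: list[str]
    x_by_level: list[tuple[int, int]]
    deepest_motif_level: int | None = None

    @property
    def is_motif_localized(self) -> bool:
        return self.deepest_motif_level is not None


@dataclass
class HierarchyTree:
    """Result of :func:`decompose`: the community tree plus hub traces."""

    root: CommunityNode
    traces: dict[str, HubTrace]
    hub_threshold: int
    rng_seed: int

    @property
    def max_level(self) -> int:
        return max(c.level for c in self.root.walk())

    @property
    def max_motif_level(self) -> int | None:
        """Deepest level at which a hub's trace ends in a motif."""
        levels = [t.deepest_motif_level for t in self.traces.values()
                  if t.deepest_motif_level is not None]
        return max(levels) if levels else None

    def community(self, cid: str) -> CommunityNode:
        for c in self.root.walk():
            if c.id == cid:
                return c
        raise KeyError(cid)

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(c: CommunityNode) -> dict:
            return {
                "id": c.id, "level": c.level, "size": len(c.members),
                "edge_count": c.edge_count, "q_of_split": c.q_of_split,
                "is_motif": c.is_motif, "members": sorted(c.members),
                "children": [enc(ch) for ch in c.children],
            }
        payload = {
            "hub_threshold": self.hub_threshold,
            "rng_seed": self.rng_seed,
            "max_level": self.max_level,
            "tree": enc(self.root),
            "hub_traces": {
                g: {
                    "degree_in_root": t.degree_in_root,
                    "path": t.path,
                    "x_by_level": t.x_by_level,
                    "deepest_motif_level": t.deepest_motif_level,
                } for g, t in sorted(self.traces.items())
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class KeyRegulatorReport:
    hub_threshold: int
    motif_localized_hubs: set[str]
    key_regulators: set[str]
    max_depth_reached: int
    pkr_profiles: dict[str, list[tuple[int, float]]]
    q_by_level: list[tuple[int, float, list[float]]]


def louvain_partition(
    net: Network, rng_seed: int = DEFAULT_SEED, n_restarts: int = 20
) -> tuple[list[set[str]], float]:
    """Two-phase Louvain on the unweighted graph, deterministic per seed.

    Louvain is a greedy heuristic whose local optimum depends on the
    sweep order, so the partition is taken as the best of ``n_restarts``
    seeded runs (seeds derived from ``rng_seed``; ties keep the earliest
    run).  Returns the partition (communities ordered by their smallest
    member id) and its Newman-Girvan modularity Q.
    """
    if net.n_edges < 1:
        raise ValueError("louvain requires at least one edge")
    best: tuple[list[set[str]], float] | None = None
    for i in range(max(1, n_restarts)):
        sub_seed = (rng_seed * 7919 + i) % (2**31)
        comms = nx.community.louvain_communities(net.graph, seed=sub_seed)
        comms = sorted((set(c) for c in comms), key=lambda c: min(c))
        q = nx.community.modularity(net.graph, comms)
        if best is None or q > best[1] + 1e-12:
            best = (comms, q)
    return best


def decompose(
    net: Network,
    hub_threshold: int | None = None,
    rng_seed: int = DEFAULT_SEED,
    max_levels: int = 30,
    hub_quantile: float | None = None,
    full: bool = False,
) -> HierarchyTree:
    """Recursively split the network into nested Louvain communities.

    Hubs are nodes whose degree in the *root* network reaches
    ``hub_threshold`` (or the top ``hub_quantile`` fraction of degrees
    when a quantile is given instead).  A community is split further when
    it contains at least one hub (always, when ``full``), has >= 3 nodes
    and >= 3 edges, is not itself a triangle motif, and Louvain proposes
    a non-trivial partition; recursion also stops at ``max_levels``.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degree()
    if hub_quantile is not None:
        if not 0 < hub_quantile < 1:
            raise ValueError("hub_quantile must be in (0, 1)")
        order = sorted(deg.values(), reverse=True)
        k = max(1, int(round(hub_quantile * len(order))))
        hub_threshold = max(order[k - 1], 1)
    if hub_threshold is None:
        raise ValueError("either hub_threshold or hub_quantile is required")
    if hub_threshold < 1:
        raise ValueError("hub_threshold must be >= 1")
    hubs = {n for n, d in deg.items() if d >= hub_threshold}
    logger.info("%s: %d hubs at degree >= %d (seed=%d)",
                net.name, len(hubs), hub_threshold, rng_seed)

    def build(members: frozenset[str], cid: str, level: int) -> CommunityNode:
        sub = induced_subgraph(net, members) if members != net.nodes else net
        node = CommunityNode(id=cid, level=level, members=members,
                             edge_count=sub.n_edges)
        if node.is_motif or len(members) < 3 or sub.n_edges < 3:
            return node
        if level >= max_levels:
            return node
        if not full and not (hubs & members):
            return node
        parts, q = louvain_partition(sub, rng_seed=rng_seed)
        if len(parts) < 2:
            return node
        node.q_of_split = q
        for i, part in enumerate(parts):
            node.children.append(
                build(frozenset(part), f"{cid}.{i}", level + 1))
        return node

    root = build(frozenset(net.nodes), "0", 0)

    traces: dict[str, HubTrace] = {}
    for hub in sorted(hubs):
        path, xs = [], []
        comm = root
        while True:
            sub_deg = _degree_within(net, comm.members, hub)
            path.append(comm.id)
            xs.append((comm.level, sub_deg))
            nxt = next((ch for ch in comm.children if hub in ch.members), None)
            if nxt is None:
                break
            comm = nxt
        traces[hub] = HubTrace(
            gene=hub, degree_in_root=deg[hub], path=path, x_by_level=xs,
            deepest_motif_level=comm.level if comm.is_motif else None,
        )
    return HierarchyTree(root=root, traces=traces,
                         hub_threshold=hub_threshold, rng_seed=rng_seed)


def _degree_within(net: Network, members: frozenset[str], node: str) -> int:
    return sum(1 for nb in net.graph.neighbors(node) if nb in members)


def motif_localized_hubs(tree: HierarchyTree) -> set[str]:
    """Hubs whose trace terminates inside a triangle motif at any level."""
    return {g for g, t in tree.traces.items() if t.is_motif_localized}


def key_regulators(tree: HierarchyTree) -> set[str]:
    """Motif-localized hubs whose motif lies at the deepest motif level."""
    deepest = tree.max_motif_level
    if deepest is None:
        raise ValueError("no key regulators identifiable: no hub ends in a motif")
    return {g for g, t in tree.traces.items()
            if t.deepest_motif_level == deepest}


def pkr_profile(tree: HierarchyTree, gene: str) -> list[tuple[int, float]]:
    """P_KR(s) = x[s]/N[s] along the gene's community path.

    x[s] is the gene's degree inside the level-s community's induced
    subgraph and N[s] that subgraph's edge count.
    """
    trace = tree.traces.get(gene)
    if trace is None:
        raise KeyError(f"{gene}: not a traced hub of this tree")
    out = []
    for (level, x), cid in zip(trace.x_by_level, trace.path):
        n_edges = tree.community(cid).edge_count
        if n_edges == 0:
            raise ValueError(f"community {cid} has no edges")
        out.append((level, x / n_edges))
    return out


def modularity_by_level(tree: HierarchyTree) -> list[tuple[int, float, list[float]]]:
    """Mean modularity of the Louvain splits applied at each level.

    Motif leaves are never split and contribute nothing (a triangle's
    trivial partition has modularity 0; it is excluded, not averaged).
    """
    by_level: dict[int, list[float]] = {}
    for comm in tree.root.walk():
        if comm.q_of_split is not None:
            by_level.setdefault(comm.level, []).append(comm.q_of_split)
    return [(lvl, sum(v) / len(v), sorted(v))
            for lvl, v in sorted(by_level.items())]


def traces_to_tsv(tree: HierarchyTree, path: str | Path) -> None:
    """Hub traces with per-level P_KR as a flat TSV (one row per hub and
    level)."""
    with open(Path(path), "w") as fh:
        fh.write("gene\tdegree_in_root\tlevel\tcommunity\tcommunity_size"
                 "\tx\tN\tp_kr\tis_motif\n")
        for gene, trace in sorted(tree.traces.items()):
            for cid, (level, x) in zip(trace.path, trace.x_by_level):
                comm = tree.community(cid)
                pkr = x / comm.edge_count if comm.edge_count else float("nan")
                fh.write(f"{gene}\t{trace.degree_in_root}\t{level}\t{cid}"
                         f"\t{len(comm.members)}\t{x}\t{comm.edge_count}"
                         f"\t{pkr:.6g}\t{int(comm.is_motif)}\n")


def key_regulator_report(tree: HierarchyTree) -> KeyRegulatorReport:
    """Assemble the motif-localized hub set, KRs, per-KR P_KR profiles
    and modularity-by-level summary for one decomposition."""
    mlh = motif_localized_hubs(tree)
    krs = key_regulators(tree)
    return KeyRegulatorReport(
        hub_threshold=tree.hub_threshold,
        motif_localized_hubs=mlh,
        key_regulators=krs,
        max_depth_reached=tree.max_level,
        pkr_profiles={g: pkr_profile(tree, g) for g in sorted(krs)},
        q_by_level=modularity_by_level(tree),
    )
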