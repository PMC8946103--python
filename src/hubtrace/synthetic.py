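"""Seeded generators for networks with the structure the pipeline assumes.

Three generators:

* :func:`ravasz_network` — the deterministic hierarchical-modular
  construction whose clustering profile decays like c(k) ~ k**-1.
* :func:`ba_network` — preferential attachment from a clique seed; the
  canonical scale-free null with (asymptotically) degree-independent
  clustering.
* :func:`planted_hub_hierarchy` — the test-bed for the hub-tracing
  pipeline: a background of communities and clique "protein complexes"
  plus, per planted triangle, nested shells of small dense blocks and a
  sanctuary of dense blocks wrapped around the hub triangle.  Hub wiring
  decays toward the triangle, so successive Louvain splits peel the
  shells and the trace terminates in the planted triangle motif; the
  planted truth (hub ids, motif members, dense-complex members, a
  hub-degree floor) is emitted alongside the graph.

All generators are pure functions of their parameters and seed (numpy
``default_rng`` streams), so emitted networks are byte-identical across
re-runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np

from hubtrace.netio import Network
from hubtrace.netio import NodeAnnotations


@dataclass
class PlantedTruth:
    """Ground truth emitted with a planted network."""

    planted_hub_ids: set[str]
    planted_motif_members: dict[int, list[tuple[str, str, str]]]
    dense_block_members: set[str]
    hub_degree_floor: int
    generator: str
    params: dict
    seed: int
    drug_gene_ids: set[str] = field(default_factory=set)

    @property
    def deepest_motif_hubs(self) -> set[str]:
        """Hubs of the triangles planted at the greatest depth."""
        deepest = max(self.planted_motif_members)
        return {g for tri in self.planted_motif_members[deepest] for g in tri}


def ravasz_network(levels: int, base: int = 5) -> Network:
    """Deterministic hierarchical-modular network.

    Level 1 is K_base; each further level replicates the current module
    ``base - 1`` times and wires every replica's peripheral nodes to the
    original central hub.  Node count is exactly ``base ** levels``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > 5:
        raise ValueError("size guard: levels > 5 would exceed base**5 nodes")
    if base < 3:
        raise ValueError("base must be >= 3")
    g = nx.complete_graph(base)
    hub = 0
    periph = set(range(1, base))
    for _ in range(2, levels + 1):
        g0 = g.copy()
        n0 = g0.number_of_nodes()
        new_periph: set[int] = set()
        for rep in range(1, base):
            off = rep * n0
            g.add_edges_from((u + off, v + off) for u, v in g0.edges)
            new_periph |= {p + off for p in periph}
        for p in new_periph:
            g.add_edge(p, hub)
        periph = new_periph
    relabeled = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
    return Network(graph=relabeled, name=f"ravasz_l{levels}_b{base}")


def ba_network(n: int, m: int, rng_seed: int = 0) -> Network:
    """Preferential attachment from an m-clique seed: exactly
    (n - m) * m + C(m, 2) edges."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    # m = 1 needs a 2-node seed (a lone node has no attachment targets);
    # K2 contributes its single edge so the count formula still holds
    seed_graph = nx.complete_graph(max(m, 2))
    g = nx.barabasi_albert_graph(n, m, seed=rng_seed, initial_graph=seed_graph)
    relabeled = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
    return Network(graph=relabeled, name=f"ba_n{n}_m{m}")


def powerlaw_samples(
    alpha: float, xmin: int, n: int, rng_seed: int = 0
) -> list[int]:
    """Exact i.i.d. draws from the discrete power law x**-alpha, x >= xmin
    (inverse transform on the Hurwitz-zeta normalised CDF)."""
    from hubtrace.scaling import sample_discrete_powerlaw

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return sample_discrete_powerlaw(alpha, xmin, n, rng).tolist()


@dataclass(frozen=True)
class HierarchyShape:
    """Shape of a planted hub hierarchy.

    Background: ``bg_blocks`` communities of ``bg_block_size`` nodes
    (edge probability ``bg_p``) sparsely coupled at ``bg_coupling``,
    plus ``complex_blocks`` much denser "protein complex" blocks — the
    dense regions in which drug-associated genes concentrate and that
    MCODE is meant to pick up.  Per planted triangle (one per entry of
    ``motif_depths``) the triangle sits inside a sanctuary of
    ``sanctuary_blocks`` dense blocks (each hub wires once into each),
    surrounded by ``depth - 2`` nested shells; ``shell_template`` lists
    the shells from the innermost outward as ``(n_blocks, block_size,
    edge_probability)``, sparser and coarser outward, so deeper shells
    are the denser, community-forming ones.  Hubs are wired into shell
    ``j`` (0 = innermost) with ``hub_shell_edges[j]`` round-robin edges
    each — decaying toward the triangle, so successive Louvain splits
    peel the shells and the triangle finally detaches with almost no
    outward edges — plus ``hub_bg_edges`` edges spread thinly over the
    background, which give hubs their high raw degree without biasing
    any single community.  ``shell_couplings[j]`` couples shell-``j``
    blocks to the whole deeper region, strictly denser inward;
    ``shell_lateral`` couples blocks of the same shell, weakly.
    """

    bg_blocks: int = 45
    bg_block_size: int = 12
    bg_p: float = 0.35
    bg_coupling: float = 0.001
    complex_blocks: int = 6
    complex_size: int = 12
    complex_p: float = 1.0
    motif_depths: tuple[int, ...] = (3,)
    sanctuary_blocks: int = 4
    sanctuary_size: int = 6
    sanctuary_p: float = 0.90
    sanctuary_coupling: float = 0.20
    shell_template: tuple[tuple[int, int, float], ...] = (
        (12, 5, 0.70), (20, 6, 0.60), (22, 7, 0.55),
    )
    hub_shell_edges: tuple[int, ...] = (6, 14, 18)
    shell_couplings: tuple[float, ...] = (0.04, 0.020, 0.015)
    shell_lateral: float = 0.015
    hub_bg_edges: int = 18
    chain_bg_bridges: int = 3

    def __post_init__(self):
        if min(self.motif_depths, default=0) < 1:
            raise ValueError("motif depths must be >= 1")
        deepest = max(self.motif_depths, default=1)
        if deepest - 2 > len(self.shell_template):
            raise ValueError(
                f"motif depth {deepest} needs {deepest - 2} shells but the "
                f"template provides {len(self.shell_template)}")
        if len(self.hub_shell_edges) < len(self.shell_template) or \
                len(self.shell_couplings) < len(self.shell_template):
            raise ValueError("hub_shell_edges and shell_couplings must cover "
                             "every template shell")
        probs = [p for _, _, p in self.shell_template]
        if any(outer >= inner for inner, outer in zip(probs[:-1], probs[1:])):
            raise ValueError(
                "degenerate probabilities: deeper (inner) shells must be "
                "denser than shallower (outer) ones")
        if probs and probs[-1] <= self.bg_p:
            raise ValueError(
                "degenerate probabilities: every shell must be denser than "
                "the background")
        cpl = list(self.shell_couplings[:len(self.shell_template)])
        if any(outer >= inner for inner, outer in zip(cpl[:-1], cpl[1:])):
            raise ValueError(
                "degenerate probabilities: shell couplings must decrease "
                "outward (deeper shells couple more densely)")


def _er_block(nodes: Sequence[str], p: float, rng: np.random.Generator,
              edges: set[tuple[str, str]]) -> None:
    """Dense Erdos-Renyi block, guaranteed connected by a chained spine."""
    order = list(nodes)
    for i, j in itertools.combinations(range(len(order)), 2):
        if rng.random() < p:
            edges.add((order[i], order[j]))
    for i in range(len(order) - 1):  # spine keeps the block connected
        edges.add((order[i], order[i + 1]))


def _couple(a: Sequence[str], b: Sequence[str], p: float,
            rng: np.random.Generator, edges: set[tuple[str, str]]) -> None:
    for u in a:
        for v in b:
            if u != v and rng.random() < p:
                edges.add((u, v) if u < v else (v, u))


def planted_hub_hierarchy(
    shape: HierarchyShape = HierarchyShape(), rng_seed: int = 0
) -> tuple[Network, PlantedTruth]:
    """Build a planted hub hierarchy; see :class:`HierarchyShape`.

    Returns the network and its :class:`PlantedTruth`.  The declared
    hub-degree floor is the midpoint between the lowest planted-hub
    degree and the highest non-hub degree; generation fails loudly if
    the two overlap (the planted hubs would not be identifiable).
    """
    rng = np.random.default_rng(rng_seed)
    edges: set[tuple[str, str]] = set()

    bg_blocks: list[list[str]] = []
    for b in range(shape.bg_blocks):
        block = [f"B{b:02d}_{i:02d}" for i in range(shape.bg_block_size)]
        _er_block(block, shape.bg_p, rng, edges)
        bg_blocks.append(block)
    # protein-complex analogues: very dense blocks hosting the
    # drug-associated genes (the regions MCODE is meant to pick up)
    cx_blocks: list[list[str]] = []
    for b in range(shape.complex_blocks):
        block = [f"C{b:02d}_{i:02d}" for i in range(shape.complex_size)]
        _er_block(block, shape.complex_p, rng, edges)
        cx_blocks.append(block)
    bg_all = [n for blk in bg_blocks + cx_blocks for n in blk]
    for i, j in itertools.combinations(range(len(bg_blocks)), 2):
        _couple(bg_blocks[i], bg_blocks[j], shape.bg_coupling, rng, edges)
    for blk in cx_blocks:  # complexes couple to the background only:
        for bgb in bg_blocks:  # two adjacent complexes would otherwise be
            _couple(blk, bgb, shape.bg_coupling, rng, edges)  # chained by MCODE
    # ring keeps the background connected; complexes are interleaved so
    # no two dense complexes sit next to each other
    ring: list[list[str]] = list(bg_blocks)
    step = max(1, len(ring) // max(1, len(cx_blocks)))
    for i, blk in enumerate(cx_blocks):
        ring.insert(min(len(ring), (i + 1) * step + i), blk)
    for i in range(len(ring)):
        u = ring[i][0]
        v = ring[(i + 1) % len(ring)][0]
        edges.add((u, v) if u < v else (v, u))

    hubs: set[str] = set()
    motifs: dict[int, list[tuple[str, str, str]]] = {}

    for t_idx, depth in enumerate(shape.motif_depths):
        tri = tuple(f"H{t_idx}_{i}" for i in range(3))
        hubs |= set(tri)
        motifs.setdefault(depth, []).append(tri)  # type: ignore[arg-type]
        for u, v in itertools.combinations(tri, 2):
            edges.add((u, v) if u < v else (v, u))

        # the sanctuary: a few small dense blocks every hub wires into
        # (one edge per block).  They keep the triangle coherent through
        # the intermediate splits, yet carry balanced modularity mass, so
        # the final small-scale split yields {triangle} + one community
        # per sanctuary block instead of carving hubs into the blocks.
        san_blocks: list[list[str]] = []
        if depth >= 2:
            for b in range(shape.sanctuary_blocks):
                blk = [f"T{t_idx}SANB{b}_{i:02d}"
                       for i in range(shape.sanctuary_size)]
                _er_block(blk, shape.sanctuary_p, rng, edges)
                san_blocks.append(blk)
            for a, b in itertools.combinations(range(len(san_blocks)), 2):
                _couple(san_blocks[a], san_blocks[b],
                        shape.sanctuary_coupling, rng, edges)
        sanctuary = [n for blk in san_blocks for n in blk]

        # shells indexed 0 (innermost, next to the sanctuary) .. depth-3
        # (outermost, peeled by the first chain split)
        shells: list[list[list[str]]] = []
        for j in range(depth - 2):
            n_blocks, size, p = shape.shell_template[j]
            shell = []
            for b in range(n_blocks):
                block = [f"T{t_idx}S{j}B{b:02d}_{i:02d}" for i in range(size)]
                _er_block(block, p, rng, edges)
                shell.append(block)
            shells.append(shell)

        # couplings: lateral (between blocks of the same shell) stay weak;
        # radial (shell to the whole deeper region: inner shells plus
        # sanctuary) decay outward, so each shell binds to the core more
        # strongly than to its siblings and the nesting is respected
        for j, shell in enumerate(shells):
            radial = shape.shell_couplings[j]
            deeper = sanctuary + [n for sh in shells[:j] for blk in sh for n in blk]
            for a, b in itertools.combinations(range(len(shell)), 2):
                _couple(shell[a], shell[b], shape.shell_lateral, rng, edges)
            if deeper:
                flat = [n for blk in shell for n in blk]
                _couple(flat, deeper, radial, rng, edges)

        # hub wiring: round-robin over the blocks of each shell, with the
        # per-shell budget hub_shell_edges[j] (small next to the triangle
        # so it can finally detach as a clean motif).  Every target node
        # takes at most one hub edge: a node wired to two hubs would ride
        # along with the triangle to the deepest level and spoil the motif.
        used: set[str] = set()

        def _wire(h: str, blk: list[str]) -> None:
            free = [v for v in blk if v not in used]
            if not free:
                return
            v = free[int(rng.integers(len(free)))]
            used.add(v)
            edges.add((h, v) if h < v else (v, h))
            # reinforce the target inside its own block: its home pull
            # must always dominate the single hub edge, or it may follow
            # the hubs to the deepest level as a motif-spoiling straggler
            mates = [w for w in blk if w != v]
            for w in (mates if len(mates) <= 2 else
                      [mates[int(rng.integers(len(mates)))] for _ in range(2)]):
                edges.add((v, w) if v < w else (w, v))

        for h in tri:
            for blk in san_blocks:
                _wire(h, blk)  # exactly one edge per hub per sanctuary block

        for j, shell in enumerate(shells):
            e_j = shape.hub_shell_edges[j]
            blocks = list(shell)
            for h_i, h in enumerate(tri):
                for k in range(e_j):
                    _wire(h, blocks[(k + h_i) % len(blocks)])

        # thin background wiring gives hubs their raw degree, round-robin
        # across background and complex blocks so hubs also touch the
        # dense drug-gene complexes; wide offsets keep the three hubs on
        # mostly disjoint blocks, so no single block accumulates enough
        # triangle edges to capture the triangle at the root split
        pool = bg_blocks + cx_blocks
        spread = max(1, len(pool) // 3)
        for h_i, h in enumerate(tri):
            for k in range(shape.hub_bg_edges):
                _wire(h, pool[(k + h_i * spread) % len(pool)])

        # bridge the chain to the background (one bridge per distinct bg
        # block, so no single background community gets a grip on it)
        outer = ([n for blk in shells[-1] for n in blk]
                 if shells else (sanctuary or list(tri)))
        spacing = max(1, len(bg_blocks) // max(1, shape.chain_bg_bridges))
        for b in range(shape.chain_bg_bridges):
            u = outer[int(rng.integers(len(outer)))]
            blk = bg_blocks[(t_idx * 3 + b * spacing) % len(bg_blocks)]
            v = blk[int(rng.integers(len(blk)))]
            edges.add((u, v) if u < v else (v, u))

    # sorted: graph insertion order must be hash-independent for
    # reproducible Louvain runs
    net = Network.from_edges(sorted(edges), name=f"planted_seed{rng_seed}")
    deg = net.degree()
    hub_min = min(deg[h] for h in hubs)
    nonhub_max = max(d for n, d in deg.items() if n not in hubs)
    if hub_min <= nonhub_max:
        raise ValueError(
            f"planted hubs not separable: min hub degree {hub_min} <= "
            f"max non-hub degree {nonhub_max}; increase hub_shell_edges")
    floor = (hub_min + nonhub_max + 1) // 2

    truth = PlantedTruth(
        planted_hub_ids=set(hubs),
        planted_motif_members=motifs,
        dense_block_members={n for blk in cx_blocks for n in blk},
        hub_degree_floor=floor,
        generator="planted_hub_hierarchy",
        params=asdict(shape),
        seed=rng_seed,
    )
    return net, truth


def annotate_drug_genes(
    net: Network,
    truth: PlantedTruth,
    frac_in_dense: float = 0.6,
    frac_background: float = 0.05,
    rng_seed: int = 0,
) -> NodeAnnotations:
    """Flag a fraction of the planted dense-block nodes (and a background
    fraction of everything else) as drug-associated; every node of the
    network receives an explicit annotation.  Updates
    ``truth.drug_gene_ids`` with the flagged set."""
    if not 0 <= frac_in_dense <= 1 or not 0 <= frac_background <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    dense = sorted(truth.dense_block_members & net.nodes)
    rest = sorted(net.nodes - truth.dense_block_members)
    flagged: set[str] = set()
    for pool, frac in ((dense, frac_in_dense), (rest, frac_background)):
        k = int(round(frac * len(pool)))
        if k:
            flagged |= set(rng.choice(pool, size=k, replace=False))
    records = {
        n: {"drug_associated": n in flagged, "extra": {}} for n in net.nodes
    }
    truth.drug_gene_ids = set(flagged)
    return NodeAnnotations(records=records)
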