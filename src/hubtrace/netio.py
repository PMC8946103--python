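"""Graph data model, edge-list / annotation I/O, and subgraph primitives.

The central container is :class:`Network`, a thin immutable-by-convention
wrapper around :class:`networkx.Graph` that enforces the simple-graph
contract every downstream stage assumes: string node identifiers, no
self-loops, no duplicate edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class AnnotationSchemaError(ValueError):
    """An annotation table is missing a required column."""


@dataclass
class Network:
    """A simple undirected labeled graph.

    Node identifiers are case-sensitive opaque strings; no gene-symbol
    normalisation is attempted.  Self-loops and duplicate edges are
    rejected at construction.  Treat instances as immutable: operations
    such as :func:`remove_nodes` return new objects.
    """

    graph: nx.Graph
    name: str = "network"

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "Network":
        """Build a Network, silently dropping self-loops and duplicates.

        Drop counts are logged at INFO level.
        """
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_loops = n_dups = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
        if n_loops or n_dups:
            logger.info(
                "%s: dropped %d self-loops, %d duplicate edges",
                name, n_loops, n_dups,
            )
        return cls(graph=g, name=name)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def __contains__(self, node: str) -> bool:
        return self.graph.has_node(node)

    def __iter__(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    def __repr__(self) -> str:
        return f"Network({self.name!r}, n={self.n_nodes}, m={self.n_edges})"


@dataclass
class NodeAnnotations:
    """Per-node annotation records keyed by node identifier.

    Lookup of an absent node yields an explicit ``None`` ("unannotated"),
    never an implicit drug-association.
    """

    records: dict[str, dict] = field(default_factory=dict)

    def is_drug_associated(self, node: str) -> bool | None:
        """True/False for annotated nodes, None for unannotated ones."""
        rec = self.records.get(node)
        if rec is None:
            return None
        return bool(rec["drug_associated"])

    @property
    def drug_genes(self) -> set[str]:
        return {n for n, r in self.records.items() if r["drug_associated"]}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, node: str) -> bool:
        return node in self.records


_TRUE = {"true", "1", "t", "yes", "y"}
_FALSE = {"false", "0", "f", "no", "n"}


def _parse_bool(raw, path: Path, line_hint: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise AnnotationSchemaError(
        f"{path}: cannot interpret drug_associated value {raw!r} ({line_hint})"
    )


def read_edge_list(
    path: str | Path, delimiter: str | None = "\t", name: str | None = None
) -> Network:
    """Read a two-column edge list (optionally with a trailing ignored
    weight column) or a three-column SIF file into a Network.

    ``delimiter=None`` splits on arbitrary whitespace.  Lines starting with
    ``#`` are comments.  Self-loops and duplicate edges are dropped with a
    log note.  A line with a single field raises
    :class:`EdgeListParseError` naming the line number; an empty file
    raises ``ValueError("no edges")``.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    is_sif = path.suffix.lower() == ".sif"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}"
                )
            if is_sif:
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF line needs 'node relation node'"
                    )
                edges.append((fields[0], fields[2]))
            else:
                edges.append((fields[0], fields[1]))
    if not edges:
        raise ValueError(f"{path}: no edges")
    return Network.from_edges(edges, name=name or path.stem)


def write_edge_list(net: Network, path: str | Path, delimiter: str = "\t") -> None:
    """Write the network as a sorted two-column edge list (round-trips
    with :func:`read_edge_list`; isolated nodes are written as comment
    metadata so node sets survive the round trip)."""
    path = Path(path)
    isolated = sorted(n for n, d in net.graph.degree() if d == 0)
    with open(path, "w") as fh:
        fh.write(f"# network: {net.name}\n")
        for n in isolated:
            fh.write(f"# isolated-node: {n}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def read_edge_list_with_isolates(
    path: str | Path, delimiter: str | None = "\t", name: str | None = None
) -> Network:
    """Like :func:`read_edge_list` but also restores ``# isolated-node:``
    comment metadata written by :func:`write_edge_list`."""
    path = Path(path)
    isolated = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# isolated-node:"):
                isolated.append(line.split(":", 1)[1].strip())
    net = read_edge_list(path, delimiter=delimiter, name=name)
    net.graph.add_nodes_from(isolated)
    return net


def read_annotations(path: str | Path) -> NodeAnnotations:
    """Read a tab-separated annotation table with header columns
    ``node`` and ``drug_associated`` (values true/false/1/0).

    Unknown columns are preserved under the record's ``extra`` mapping.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "node" not in cols or "drug_associated" not in cols:
        raise AnnotationSchemaError(
            f"{path}: header must contain 'node' and 'drug_associated', "
            f"got {list(df.columns)}"
        )
    extra_cols = [c for c in df.columns
                  if c not in (cols["node"], cols["drug_associated"])]
    records: dict[str, dict] = {}
    for i, row in df.iterrows():
        node = str(row[cols["node"]]).strip()
        flag = _parse_bool(row[cols["drug_associated"]], path, f"row {i}")
        records[node] = {
            "drug_associated": flag,
            "extra": {c: row[c] for c in extra_cols},
        }
    return NodeAnnotations(records=records)


def write_annotations(ann: NodeAnnotations, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node\tdrug_associated\n")
        for node in sorted(ann.records):
            flag = "true" if ann.records[node]["drug_associated"] else "false"
            fh.write(f"{node}\t{flag}\n")


def induced_subgraph(net: Network, members: set[str] | Iterable[str]) -> Network:
    """Subgraph on exactly ``members`` with every edge of ``net`` whose
    endpoints both lie in ``members``."""
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    missing = members - net.nodes
    if missing:
        raise ValueError(f"members not in network: {sorted(missing)[:10]}")
    # build in sorted order: node insertion order must not depend on set
    # iteration (hash randomisation), or seeded Louvain runs would differ
    # between processes
    sub = nx.Graph()
    sub.add_nodes_from(sorted(members))
    sub.add_edges_from(
        (u, v) for u, v in net.graph.edges(sorted(members))
        if u in members and v in members
    )
    return Network(graph=sub, name=f"{net.name}|sub{len(members)}")


def remove_nodes(net: Network, victims: set[str] | Iterable[str]) -> Network:
    """Return a new Network without ``victims`` or any edge touching them.

    Nodes isolated by the removal are retained with degree 0; the count of
    newly isolated nodes is logged.
    """
    victims = set(victims)
    missing = victims - net.nodes
    if missing:
        raise ValueError(f"victims not in network: {sorted(missing)[:10]}")
    if victims == net.nodes:
        raise ValueError("empty result: cannot remove every node")
    g = net.graph.copy()
    g.remove_nodes_from(victims)
    newly_isolated = sum(
        1 for n, d in g.degree()
        if d == 0 and net.graph.degree(n) > 0
    )
    if newly_isolated:
        logger.info("%s: removal isolated %d nodes", net.name, newly_isolated)
    return Network(graph=g, name=f"{net.name}-ko{len(victims)}")


def largest_component(net: Network) -> Network:
    """The induced subgraph on the largest connected component (ties
    broken by smallest member id for determinism)."""
    comps = sorted(
        nx.connected_components(net.graph),
        key=lambda c: (-len(c), min(c)),
    )
    if not comps:
        raise ValueError("empty network")
    return induced_subgraph(net, comps[0])
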