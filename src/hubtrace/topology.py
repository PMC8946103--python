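"""The six degree-dependent topological measures of a PPI network.

Node-level measures: local clustering c_i, closeness C_C, eigenvector C_E
and betweenness C_B centralities.  Degree-aggregated profiles: the degree
distribution p(k), mean clustering by degree c(k), and neighbourhood
connectivity C_N(k) (mean degree of a node's neighbours, averaged over
nodes of degree k).  Any node measure can additionally be binned by exact
degree class with :func:`bin_measure_by_degree`.

Conventions (documented because degenerate inputs are common after
knockouts): closeness and betweenness are computed per connected
component, so no cross-component infinities arise; eigenvector centrality
lives on the largest component with zeros elsewhere; c_i is defined as 0
for nodes of degree < 2 but such nodes are excluded from the c(k)
profile, where the measure is undefined.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from hubtrace.netio import Network


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the iteration count."""

    def __init__(self, max_iter: int):
        super().__init__(f"eigenvector power iteration failed within {max_iter} iterations")
        self.max_iter = max_iter


@dataclass(frozen=True)
class NodeMeasure:
    """A named real-valued measure with one finite value per node."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        bad = {n: v for n, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"{self.name}: non-finite values for {list(bad)[:5]}")

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write(f"node\t{self.name}\n")
            for n in sorted(self.values):
                fh.write(f"{n}\t{self.values[n]:.10g}\n")


@dataclass(frozen=True)
class DegreeProfile:
    """A measure aggregated over exact degree classes.

    ``entries`` is a sorted tuple of ``(k, value, count)`` with strictly
    increasing k, where ``count`` is the number of nodes contributing to
    the degree-k mean.
    """

    name: str
    entries: tuple[tuple[int, float, int], ...]

    def __post_init__(self):
        ks = [k for k, _, _ in self.entries]
        if ks != sorted(set(ks)):
            raise ValueError(f"{self.name}: k values must be strictly increasing")

    @property
    def ks(self) -> np.ndarray:
        return np.array([k for k, _, _ in self.entries], dtype=int)

    @property
    def vals(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.entries], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, _, c in self.entries], dtype=int)

    def as_dict(self) -> dict[int, float]:
        return {k: v for k, v, _ in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write(f"k\t{self.name}\tcount\n")
            for k, v, c in self.entries:
                fh.write(f"{k}\t{v:.10g}\t{c}\n")


def _profile_from_groups(name: str, by_k: dict[int, list[float]]) -> DegreeProfile:
    entries = tuple(
        (k, float(np.mean(vs)), len(vs)) for k, vs in sorted(by_k.items())
    )
    return DegreeProfile(name=name, entries=entries)


def degree_distribution(net: Network) -> DegreeProfile:
    """p(k) = n_k / N, the fraction of nodes of each observed degree.

    Includes k = 0 when isolated nodes exist; values sum to 1.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    counts: dict[int, int] = defaultdict(int)
    for _, d in net.graph.degree():
        counts[d] += 1
    n = net.n_nodes
    entries = tuple((k, c / n, c) for k, c in sorted(counts.items()))
    return DegreeProfile(name="p(k)", entries=entries)


def local_clustering(net: Network) -> NodeMeasure:
    """Local clustering c_i = 2 m_i / (k_i (k_i - 1)); 0 for k_i < 2."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return NodeMeasure(name="c", values=nx.clustering(net.graph))


def clustering_by_degree(net: Network) -> DegreeProfile:
    """c(k): mean local clustering over nodes of degree k, for k >= 2.

    Nodes with degree < 2, where the coefficient is undefined, are
    excluded from the profile (they are reported as c_i = 0 by
    :func:`local_clustering`).
    """
    cm = local_clustering(net)
    deg = net.degree()
    by_k: dict[int, list[float]] = defaultdict(list)
    for n, d in deg.items():
        if d >= 2:
            by_k[d].append(cm[n])
    return _profile_from_groups("c(k)", by_k)


def neighborhood_connectivity(net: Network) -> DegreeProfile:
    """C_N(k): mean over degree-k nodes of the average degree of their
    neighbours.  Isolated nodes are excluded."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degree()
    by_k: dict[int, list[float]] = defaultdict(list)
    for n, d in deg.items():
        if d == 0:
            continue
        mean_nbr = float(np.mean([deg[v] for v in net.graph.neighbors(n)]))
        by_k[d].append(mean_nbr)
    return _profile_from_groups("C_N(k)", by_k)


def closeness_centrality(net: Network) -> NodeMeasure:
    """C_C(m) = n / sum_j d_mj over the n other nodes of m's component.

    Computed per component; an isolated node scores 0.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    vals = nx.closeness_centrality(net.graph, wf_improved=False)
    return NodeMeasure(name="C_C", values=vals)


def eigenvector_centrality(
    net: Network, tol: float = 1e-10, max_iter: int = 1000
) -> NodeMeasure:
    """Principal adjacency eigenvector of the largest component, scaled
    to unit Euclidean norm, with zeros outside that component.

    Raises :class:`ConvergenceError` when power iteration does not reach
    ``tol`` within ``max_iter`` iterations.
    """
    if net.n_edges < 1:
        raise ValueError("eigenvector centrality needs at least one edge")
    comps = sorted(nx.connected_components(net.graph),
                   key=lambda c: (-len(c), min(c)))
    lcc = net.graph.subgraph(comps[0])
    try:
        vals = nx.eigenvector_centrality(lcc, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(max_iter) from exc
    # networkx normalises to unit L2 already; renormalise defensively
    vec = np.array(list(vals.values()))
    norm = float(np.linalg.norm(vec))
    out = {n: 0.0 for n in net.graph.nodes}
    for n, v in vals.items():
        out[n] = abs(v) / norm
    return NodeMeasure(name="C_E", values=out)


def betweenness_centrality(net: Network, normalized: bool = True) -> NodeMeasure:
    """C_B(n_i) = sum over unordered pairs j<k (both != i) of the fraction
    of j-k geodesics passing through i.

    When ``normalized`` the raw value is divided by (n-1)(n-2)/2 with n
    the size of the node's connected component, so the maximum (a star
    centre) is 1 regardless of component count.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    out: dict[str, float] = {}
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        vals = nx.betweenness_centrality(sub, normalized=normalized)
        out.update(vals)
    return NodeMeasure(name="C_B", values=out)


def bin_measure_by_degree(net: Network, m: NodeMeasure) -> DegreeProfile:
    """Mean of a node measure over each exact degree class k >= 1."""
    deg = net.degree()
    missing = set(deg) - set(m.values)
    if missing:
        raise ValueError(f"measure {m.name} undefined for {sorted(missing)[:5]}")
    by_k: dict[int, list[float]] = defaultdict(list)
    for n, d in deg.items():
        if d >= 1:
            by_k[d].append(m.values[n])
    return _profile_from_groups(f"{m.name}(k)", by_k)
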