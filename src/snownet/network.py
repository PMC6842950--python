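"""Signed co-variance networks and their comparison metrics.

A network is built from the significant LSA pairs of one sampling
period: nodes are the OTUs participating in at least one significant
pair, edges carry the association sign and the unsigned score as
weight.  The summary metrics are the standard descriptors used to
contrast cooperation-dominated (dense, connected) versus
competition-dominated (sparse, modular) co-occurrence networks, plus a
size-standardized positive-interaction ratio: the number of positive
edges divided by the number of OTU pairs C(n, 2) available to the core
community, which makes networks built from cores of different sizes
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import networkx as nx

from .lsa import LsaPair

__all__ = [
    "build_network",
    "network_summary",
    "positive_ratio",
    "NetworkSummary",
]


@dataclass
class NetworkSummary:
    """Topology descriptors of one co-variance network.

    ``None`` marks a metric undefined for the graph at hand (e.g. any
    metric on an empty network, modularity of an edgeless one).
    """

    n_nodes: int
    n_pos_edges: int
    n_neg_edges: int
    avg_degree: float | None
    density: float | None
    transitivity: float | None
    modularity: float | None
    vertex_connectivity: int | None
    avg_closeness: float | None
    avg_edge_betweenness: float | None

    @property
    def n_edges(self) -> int:
        return self.n_pos_edges + self.n_neg_edges


def build_network(
    pairs: list[LsaPair], include_negative: bool = True, period: str | None = None
) -> nx.Graph:
    """Assemble a simple signed graph from significant LSA pairs.

    Only OTUs that participate in at least one retained pair become
    nodes; core OTUs without significant partners are not isolated
    vertices.  ``include_negative=False`` drops the sign = -1 edges
    (sensitivity variant for topology metrics).
    """
    g = nx.Graph(period=period)
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = tuple(sorted((pair.otu_i, pair.otu_j)))
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        if pair.sign == -1 and not include_negative:
            continue
        g.add_edge(
            pair.otu_i,
            pair.otu_j,
            sign=pair.sign,
            weight=abs(pair.score),
            score=pair.score,
            p_value=pair.p_value,
        )
    return g


def _modularity(g: nx.Graph) -> float | None:
    """Newman-Girvan Q under greedy agglomerative maximization.

    Nodes are visited in sorted order so ties break lexicographically
    and the partition is deterministic.
    """
    if g.number_of_edges() == 0:
        return None
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in g.edges()))
    communities = nx.community.greedy_modularity_communities(h)
    return float(nx.community.modularity(h, communities))


def network_summary(g: nx.Graph) -> NetworkSummary:
    """Compute the comparison metrics for one network.

    Sign attributes are ignored for topology (negative edges count as
    edges); closeness is the within-component harmonic convention of
    Wasserman-Faust (each node's closeness is scaled by the fraction of
    the graph it can reach), so disconnected networks are handled
    without infinities; edge betweenness is unnormalized shortest-path
    load, averaged over edges.
    """
    n = g.number_of_nodes()
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s == 1)
    n_neg = sum(1 for s in signs if s == -1)
    if n == 0:
        return NetworkSummary(
            n_nodes=0,
            n_pos_edges=0,
            n_neg_edges=0,
            avg_degree=None,
            density=None,
            transitivity=None,
            modularity=None,
            vertex_connectivity=None,
            avg_closeness=None,
            avg_edge_betweenness=None,
        )
    m = g.number_of_edges()
    avg_degree = 2.0 * m / n
    density = nx.density(g) if n > 1 else 0.0
    transitivity = nx.transitivity(g)
    modularity = _modularity(g)
    vertex_connectivity = int(nx.node_connectivity(g)) if n > 1 else 0
    closeness = nx.closeness_centrality(g, wf_improved=True)
    avg_closeness = sum(closeness.values()) / n
    if m > 0:
        ebc = nx.edge_betweenness_centrality(g, normalized=False)
        avg_edge_betweenness = sum(ebc.values()) / m
    else:
        avg_edge_betweenness = None
    return NetworkSummary(
        n_nodes=n,
        n_pos_edges=n_pos,
        n_neg_edges=n_neg,
        avg_degree=avg_degree,
        density=density,
        transitivity=transitivity,
        modularity=modularity,
        vertex_connectivity=vertex_connectivity,
        avg_closeness=avg_closeness,
        avg_edge_betweenness=avg_edge_betweenness,
    )


def positive_ratio(n_pos_edges: int, n_core_otus: int) -> float:
    """Positive edges standardized by all possible core-OTU pairs.

    ``n_pos_edges / C(n_core_otus, 2)`` — the cooperation index that
    lets networks from core communities of different sizes be compared
    on a common scale.
    """
    if n_core_otus < 2:
        raise ValueError("need at least 2 core OTUs")
    total = comb(n_core_otus, 2)
    if not 0 <= n_pos_edges <= total:
        raise ValueError(
            f"n_pos_edges={n_pos_edges} outside [0, C({n_core_otus},2)={total}]"
        )
    return n_pos_edges / total
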