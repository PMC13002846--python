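"""Weighted disease co-occurrence networks.

Nodes are 3-character ICD-10 categories; an edge's weight is the number of
transactions (patients) in which both categories co-occur. Two
edge-selection policies are supported: the top-k edges by weight (used for
per-period networks, k = 20) and a node budget that adds ranked edges until
the network holds between ``node_min`` and ``node_max`` nodes (24-34 for the
overall network). Node metrics are degree, weighted degree and normalized
betweenness centrality on the unweighted retained topology; network-level
summaries are node/edge counts, density, average weighted degree and mean
local clustering. Networks export to GEXF, GraphML or an edge-list CSV.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .ehr_coding import TransactionSet
from .errors import ComorbnetError

__all__ = [
    "CoEdge",
    "EdgeSelectionPolicy",
    "NetworkSummary",
    "ComorbidityNetwork",
    "cooccurrence_edges",
    "build_network",
    "betweenness_centrality",
    "network_summary",
    "export_network",
]


@dataclass(frozen=True)
class CoEdge:
    """One undirected co-occurrence edge, endpoints in lexicographic order."""

    u: str
    v: str
    weight: int

    def __post_init__(self):
        if self.u >= self.v:
            raise ComorbnetError(f"edge endpoints must satisfy u < v: {self.u}, {self.v}")
        if self.weight < 1:
            raise ComorbnetError(f"edge weight must be >= 1, got {self.weight}")


@dataclass(frozen=True)
class EdgeSelectionPolicy:
    """``top_k_edges`` keeps the k heaviest edges; ``node_budget`` adds ranked
    edges until node_min <= nodes <= node_max, skipping edges that would
    overshoot node_max."""

    mode: str = "top_k_edges"
    k: int = 20
    node_min: int = 24
    node_max: int = 34

    def __post_init__(self):
        if self.mode not in ("top_k_edges", "node_budget"):
            raise ComorbnetError(f"unknown edge selection mode: {self.mode!r}")
        if self.k < 1:
            raise ComorbnetError(f"k must be >= 1, got {self.k}")
        if self.node_min > self.node_max:
            raise ComorbnetError(
                f"node_min {self.node_min} > node_max {self.node_max}"
            )


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    avg_weighted_degree: float
    avg_clustering: float


@dataclass
class ComorbidityNetwork:
    """A retained co-occurrence graph plus its node metrics and summary.

    ``nodes`` is a table with columns category, degree, weighted_degree,
    betweenness; ``graph`` the underlying weighted :class:`networkx.Graph`.
    """

    graph: nx.Graph
    edges: tuple[CoEdge, ...]
    nodes: pd.DataFrame
    summary: NetworkSummary


def cooccurrence_edges(transactions: TransactionSet) -> list[CoEdge]:
    """Count pairwise co-occurrence over transactions.

    weight(u, v) = number of transactions containing both u and v; pairs that
    never co-occur are omitted. Sorted by descending weight, then
    lexicographic pair — the ranking contract the selection policies rely on.
    """
    if transactions.n < 1:
        raise ComorbnetError("cannot count co-occurrence on an empty transaction set")
    counts: Counter[tuple[str, str]] = Counter()
    for _tid, items in transactions.transactions:
        counts.update(combinations(sorted(items), 2))
    edges = [CoEdge(u, v, w) for (u, v), w in counts.items()]
    edges.sort(key=lambda e: (-e.weight, e.u, e.v))
    return edges


def _node_budget_select(edges: list[CoEdge], node_min: int, node_max: int) -> list[CoEdge]:
    kept: list[CoEdge] = []
    nodes: set[str] = set()
    for edge in edges:
        new = {edge.u, edge.v} - nodes
        if len(nodes) + len(new) > node_max:
            continue  # skip-and-continue: later edges may fit the budget
        kept.append(edge)
        nodes.update(new)
        if len(nodes) >= node_min:
            break
    return kept


def build_network(
    edges: list[CoEdge], policy: EdgeSelectionPolicy = EdgeSelectionPolicy()
) -> ComorbidityNetwork:
    """Apply an edge-selection policy and compute node/graph metrics."""
    if not edges:
        raise ComorbnetError("cannot build a network from an empty edge list")
    ranked = sorted(edges, key=lambda e: (-e.weight, e.u, e.v))
    if policy.mode == "top_k_edges":
        kept = ranked[: policy.k]
    else:
        kept = _node_budget_select(ranked, policy.node_min, policy.node_max)

    graph = nx.Graph()
    for edge in kept:
        graph.add_edge(edge.u, edge.v, weight=edge.weight)

    betweenness = betweenness_centrality(graph)
    node_rows = [
        {
            "category": node,
            "degree": graph.degree(node),
            "weighted_degree": graph.degree(node, weight="weight"),
            "betweenness": betweenness[node],
        }
        for node in sorted(graph.nodes)
    ]
    nodes = pd.DataFrame(
        node_rows, columns=["category", "degree", "weighted_degree", "betweenness"]
    ).sort_values(
        ["weighted_degree", "category"], ascending=[False, True]
    ).reset_index(drop=True)

    return ComorbidityNetwork(
        graph=graph,
        edges=tuple(kept),
        nodes=nodes,
        summary=network_summary(graph),
    )


def betweenness_centrality(graph: nx.Graph | ComorbidityNetwork) -> dict[str, float]:
    """Normalized betweenness on the unweighted retained topology.

    Shortest paths are hop-count geodesics with fractional credit for
    equal-length multiplicities (Brandes accumulation); normalization is by
    (n-1)(n-2)/2. With fewer than 3 nodes every value is 0 (degenerate
    normalizer). Disconnected graphs are handled per component pair.
    """
    g = graph.graph if isinstance(graph, ComorbidityNetwork) else graph
    if g.number_of_nodes() < 3:
        return {node: 0.0 for node in g.nodes}
    return nx.betweenness_centrality(g, normalized=True, weight=None)


def network_summary(graph: nx.Graph | ComorbidityNetwork) -> NetworkSummary:
    """Node/edge counts, density, mean weighted degree, mean local clustering."""
    g = graph.graph if isinstance(graph, ComorbidityNetwork) else graph
    n = g.number_of_nodes()
    if n < 2:
        raise ComorbnetError(f"network summary needs >= 2 nodes, got {n}")
    weighted_degrees = [d for _node, d in g.degree(weight="weight")]
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density=nx.density(g),
        avg_weighted_degree=sum(weighted_degrees) / n,
        avg_clustering=nx.average_clustering(g),  # unweighted; degree<2 -> 0
    )


def export_network(
    network: ComorbidityNetwork, path: str | Path, format: str = "gexf"
) -> None:
    """Write the network as GEXF (Gephi-compatible), GraphML or edge-list CSV.

    Graph exports carry node attributes degree, weighted_degree and
    betweenness, and the edge attribute weight; the CSV has columns
    source, target, weight.
    """
    path = Path(path)
    if format == "edge_csv":
        pd.DataFrame(
            [{"source": e.u, "target": e.v, "weight": e.weight} for e in network.edges],
            columns=["source", "target", "weight"],
        ).to_csv(path, index=False)
        return
    if format not in ("gexf", "graphml"):
        raise ComorbnetError(f"unknown export format: {format!r}")
    g = network.graph.copy()
    attrs = network.nodes.set_index("category")
    for node in g.nodes:
        g.nodes[node]["degree"] = int(attrs.loc[node, "degree"])
        g.nodes[node]["weighted_degree"] = float(attrs.loc[node, "weighted_degree"])
        g.nodes[node]["betweenness"] = float(attrs.loc[node, "betweenness"])
    if format == "gexf":
        nx.write_gexf(g, path)
    else:
        nx.write_graphml(g, path)
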