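"""Global and per-element topology metrics of a correlation network.

The metrics mirror what Cytoscape's NetworkAnalyzer reports for an
undirected simple graph:

* global — vertex/edge counts, density 2e/(v(v-1)), diameter (largest
  connected component, unweighted hops), global transitivity
  3*triangles/triples, average shortest path over all connected pairs,
  number of connected components;
* per vertex — degree, betweenness centrality normalized by (v-1)(v-2)/2
  over the whole graph, local clustering coefficient;
* per edge — unnormalized edge betweenness (fractional shortest-path
  counts);
* an optional log-log least-squares power-law fit to the degree histogram.

All shortest paths are unweighted: correlation weights are attributes of
edges, not distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TopologyReport",
    "density",
    "vertex_degrees",
    "betweenness_centrality",
    "edge_betweenness",
    "clustering_coefficients",
    "transitivity",
    "mean_clustering",
    "diameter",
    "average_shortest_path",
    "fit_power_law",
    "analyze",
    "rank_hubs",
]


def density(net: nx.Graph) -> float:
    """Ratio of existing edges to all possible edges, 2e/(v(v-1)).

    Undefined (NaN) for fewer than 2 vertices.
    """
    v = net.number_of_nodes()
    if v < 2:
        return float("nan")
    return 2.0 * net.number_of_edges() / (v * (v - 1))


def vertex_degrees(net: nx.Graph) -> dict:
    """Number of incident edges per vertex."""
    return dict(net.degree())


def betweenness_centrality(net: nx.Graph) -> dict:
    """Normalized vertex betweenness over the whole graph.

    Fractional shortest-path pass-through counts divided by (v-1)(v-2)/2,
    the number of vertex pairs excluding the focal vertex; unreachable pairs
    contribute nothing. All zeros for fewer than 3 vertices.
    """
    v = net.number_of_nodes()
    if v < 3:
        return {n: 0.0 for n in net.nodes}
    return nx.betweenness_centrality(net, normalized=True)


def edge_betweenness(net: nx.Graph) -> dict:
    """Unnormalized fractional shortest-path counts through each edge."""
    raw = nx.edge_betweenness_centrality(net, normalized=False)
    return {frozenset(e): val for e, val in raw.items()}


def clustering_coefficients(net: nx.Graph) -> dict:
    """Local clustering coefficient: realized fraction of neighbor pairs.

    Vertices of degree < 2 get 0.
    """
    return nx.clustering(net)


def transitivity(net: nx.Graph) -> tuple[float, bool]:
    """Global transitivity 3*triangles / connected triples.

    Returns ``(value, defined)``; when the graph has no connected triple the
    ratio is undefined and reported as ``(0.0, False)``.
    """
    triples = sum(d * (d - 1) // 2 for _, d in net.degree())
    if triples == 0:
        return 0.0, False
    return nx.transitivity(net), True


def mean_clustering(net: nx.Graph) -> float:
    """Mean local clustering coefficient (distinct from global transitivity)."""
    if net.number_of_nodes() == 0:
        return float("nan")
    return float(np.mean(list(clustering_coefficients(net).values())))


def _components(net: nx.Graph) -> list:
    return [net.subgraph(c) for c in nx.connected_components(net)]


def diameter(net: nx.Graph) -> tuple[int, int]:
    """Maximum eccentricity over the largest connected component.

    Shortest paths are unweighted hop counts. Returns
    ``(diameter, component_count)`` so callers can see when the graph was
    disconnected and the value refers to the largest component only. When
    several components tie for largest, the maximum diameter among them is
    reported.
    """
    if net.number_of_edges() == 0:
        raise ValueError("diameter requires at least one edge")
    comps = _components(net)
    top = max(c.number_of_nodes() for c in comps)
    diam = max(nx.diameter(c) for c in comps if c.number_of_nodes() == top)
    return diam, len(comps)


def average_shortest_path(net: nx.Graph) -> float:
    """Mean hop distance over all connected ordered vertex pairs.

    Unreachable pairs are excluded; computed over the whole graph, so every
    component contributes its pairs to one pooled mean. NaN when no pair is
    connected.
    """
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        return float("nan")
    return total / count


def fit_power_law(net: nx.Graph) -> tuple[float, float]:
    """Least-squares power-law fit to the degree distribution.

    Fits a line to log(count) vs log(degree) over the non-zero histogram
    bins (degrees >= 1) and returns ``(exponent, r_squared)`` where the
    exponent is the magnitude of the slope. Requires at least 3 distinct
    positive degree values; otherwise returns ``(nan, nan)``.
    """
    degs = np.array([d for _, d in net.degree() if d > 0])
    if degs.size == 0:
        return float("nan"), float("nan")
    uniq, counts = np.unique(degs, return_counts=True)
    if uniq.size < 3:
        return float("nan"), float("nan")
    x = np.log(uniq.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    corr = np.corrcoef(x, y)[0, 1]
    return float(abs(slope)), float(corr**2)


@dataclass
class TopologyReport:
    """Aggregated topology metrics of one network.

    ``global_metrics`` is a plain dict; ``vertex_table`` one row per vertex
    (degree, betweenness, clustering, optional compound class), sorted as
    hub ranking: betweenness descending, then degree descending, then label;
    ``edge_betweenness`` maps frozenset pairs to unnormalized counts.
    """

    global_metrics: dict
    vertex_table: pd.DataFrame
    edge_betweenness: dict
    power_law: tuple = (float("nan"), float("nan"))

    @property
    def vertex_count(self) -> int:
        return int(self.global_metrics["vertex_count"])

    @property
    def edge_count(self) -> int:
        return int(self.global_metrics["edge_count"])


def analyze(net: nx.Graph) -> TopologyReport:
    """Compute every topology metric and return one deterministic report.

    The per-vertex table is ordered by the hub ranking (betweenness desc,
    degree desc, label asc), so repeated runs on the same graph produce
    identical output.
    """
    v = net.number_of_nodes()
    e = net.number_of_edges()
    deg = vertex_degrees(net)
    btw = betweenness_centrality(net)
    clus = clustering_coefficients(net)
    trans, trans_defined = transitivity(net) if v else (0.0, False)

    if e > 0:
        diam, ncomp = diameter(net)
        aspl = average_shortest_path(net)
    else:
        diam, ncomp, aspl = 0, v, float("nan")

    rows = [
        {
            "vertex": n,
            "compound_class": net.nodes[n].get("compound_class", ""),
            "degree": deg[n],
            "betweenness": btw[n],
            "clustering": clus[n],
        }
        for n in net.nodes
    ]
    table = pd.DataFrame(
        rows, columns=["vertex", "compound_class", "degree", "betweenness",
                       "clustering"]
    )
    if len(table):
        table = table.sort_values(
            by=["betweenness", "degree", "vertex"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)

    return TopologyReport(
        global_metrics={
            "vertex_count": v,
            "edge_count": e,
            "density": density(net),
            "diameter": diam,
            "transitivity": trans,
            "transitivity_defined": trans_defined,
            "mean_clustering": mean_clustering(net) if v else float("nan"),
            "average_shortest_path": aspl,
            "connected_component_count": ncomp,
        },
        vertex_table=table,
        edge_betweenness=edge_betweenness(net),
        power_law=fit_power_law(net),
    )


def rank_hubs(report: TopologyReport) -> list:
    """Vertices in hub order: betweenness desc, degree desc, label asc."""
    return list(report.vertex_table["vertex"])
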