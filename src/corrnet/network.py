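"""Edge selection by the r/p threshold rule and network set operations.

An edge between two variables exists when the magnitude of their correlation
reaches the critical value ``r_min`` AND its (adjusted) p-value falls below
``p_max`` — the indicator ``|r| >= R and p < P`` applied to every unique
pair. Selected edges form an undirected simple graph whose vertices are the
variables that take part in at least one edge; variables with no significant
correlation never enter the network.

Condition-specific networks are compared with set operations on the edge
sets (identity of an edge = its unordered label pair; weights are ignored
for membership): union, intersection and difference. Vertices left with no
incident edge after an operation are dropped, which is what shrinks the
vertex set of a difference network relative to its minuend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .correlation import CorrelationResult

__all__ = [
    "Thresholds",
    "EdgeRecord",
    "EdgeTable",
    "select_edges",
    "build_network",
    "network_union",
    "network_intersection",
    "network_difference",
]


@dataclass(frozen=True)
class Thresholds:
    """Critical values for edge selection.

    ``r_min`` is the minimum correlation magnitude (inclusive by default:
    |r| >= r_min), ``p_max`` the significance cutoff (strict: p < p_max), and
    ``use_adjusted`` chooses the adjusted p-values (q) over the raw ones.
    ``r_inclusive`` / ``p_inclusive`` flip the comparison at exact ties.
    """

    r_min: float = 0.7
    p_max: float = 0.05
    use_adjusted: bool = True
    r_inclusive: bool = True
    p_inclusive: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must be in [0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")

    def passes(self, r: float, p: float) -> bool:
        if math.isnan(r) or math.isnan(p):
            return False
        r_ok = abs(r) >= self.r_min if self.r_inclusive else abs(r) > self.r_min
        p_ok = p <= self.p_max if self.p_inclusive else p < self.p_max
        return r_ok and p_ok


@dataclass(frozen=True)
class EdgeRecord:
    """One significant unordered variable pair with its statistics."""

    source: str
    target: str
    r: float
    p_raw: float = float("nan")
    p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop edge: {self.source!r}")

    @property
    def key(self) -> frozenset:
        """Unordered identity of the edge."""
        return frozenset((self.source, self.target))

    @property
    def label(self) -> str:
        """Concatenated display label, e.g. ``"A-B"``."""
        return f"{self.source}-{self.target}"


class EdgeTable:
    """An ordered collection of unique unordered edges.

    Duplicate unordered pairs are rejected on append; iteration order is
    insertion order, which keeps file output deterministic.
    """

    def __init__(self, edges=()):
        self._edges: list[EdgeRecord] = []
        self._keys: set[frozenset] = set()
        for e in edges:
            self.append(e)

    def append(self, edge: EdgeRecord) -> None:
        if edge.key in self._keys:
            raise ValueError(f"duplicate unordered pair: {edge.label}")
        self._edges.append(edge)
        self._keys.add(edge.key)

    def __iter__(self):
        return iter(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._keys

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeTable):
            return NotImplemented
        return self._edges == other._edges

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": e.source, "target": e.target, "r": e.r,
                 "p_raw": e.p_raw, "p_adj": e.p_adj}
                for e in self._edges
            ],
            columns=["source", "target", "r", "p_raw", "p_adj"],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EdgeTable({len(self)} edges)"


def select_edges(result: CorrelationResult, thresholds: Thresholds | None = None,
                 **kwargs) -> EdgeTable:
    """Apply the threshold rule to every unique pair of a correlation result.

    Keyword arguments (``r_min``, ``p_max``, ``use_adjusted``, ...) build a
    :class:`Thresholds` when none is given. Pairs with undefined r or p are
    never selected. The sign of r is retained on the edge.
    """
    t = thresholds if thresholds is not None else Thresholds(**kwargs)
    ids = result.variable_ids
    r = result.r.to_numpy()
    p_raw = result.p_raw.to_numpy()
    p_adj = result.p_adj.to_numpy()
    p_sel = p_adj if t.use_adjusted else p_raw
    table = EdgeTable()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if t.passes(r[i, j], p_sel[i, j]):
                table.append(
                    EdgeRecord(
                        source=str(ids[i]),
                        target=str(ids[j]),
                        r=float(r[i, j]),
                        p_raw=float(p_raw[i, j]),
                        p_adj=float(p_adj[i, j]),
                    )
                )
    return table


def build_network(edges: EdgeTable) -> nx.Graph:
    """Build the undirected simple graph of an edge table.

    Vertices are exactly the labels occurring in at least one edge; the
    correlation coefficient is stored as edge attribute ``weight`` (and the
    p-values as ``p_raw`` / ``p_adj`` when present). A duplicate unordered
    pair with a conflicting r is rejected.
    """
    g = nx.Graph()
    for e in edges:
        if g.has_edge(e.source, e.target):
            old = g.edges[e.source, e.target].get("weight")
            if old is not None and not math.isclose(old, e.r, abs_tol=1e-12):
                raise ValueError(
                    f"conflicting weights for pair {e.label}: {old} vs {e.r}"
                )
            continue
        g.add_edge(e.source, e.target, weight=e.r, p_raw=e.p_raw, p_adj=e.p_adj)
    return g


def _drop_isolates(g: nx.Graph) -> nx.Graph:
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def network_union(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edges present in either network; weights from ``a`` when shared."""
    g = nx.Graph()
    for u, v, d in b.edges(data=True):
        g.add_edge(u, v, **d)
    for u, v, d in a.edges(data=True):
        g.add_edge(u, v, **d)  # a overwrites b on shared edges
    return _drop_isolates(g)


def network_intersection(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edges present in both networks (unordered label match), weights from ``a``."""
    g = nx.Graph()
    for u, v, d in a.edges(data=True):
        if b.has_edge(u, v):
            g.add_edge(u, v, **d)
    return _drop_isolates(g)


def network_difference(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edges of ``a`` absent from ``b``; vertices with no retained edge are dropped.

    This is the condition-specific ("unique interactions") network: comparing
    two condition networks, the difference keeps only the edges unique to the
    first condition, and any vertex left isolated by the subtraction leaves
    the graph.
    """
    g = nx.Graph()
    for u, v, d in a.edges(data=True):
        if not b.has_edge(u, v):
            g.add_edge(u, v, **d)
    return _drop_isolates(g)
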