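"""Model/Results facade over the correlation-network pipeline.

:class:`CorrelationNetworkModel` wraps a data matrix together with the
statistical choices (correlation type, multiplicity adjustment, pairwise
completeness policy); :meth:`~CorrelationNetworkModel.fit` applies the edge
threshold rule and returns a :class:`CorrelationNetworkResults` carrying the
correlation matrices, the selected edges, the network, its topology report
and a printable summary. Two fitted results can be compared with
union/intersection/difference set operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import io as io_formats
from .correlation import CorrelationResult, correlate, normality_screen
from .datamatrix import DataMatrix
from .network import (EdgeTable, Thresholds, build_network,
                      network_difference, network_intersection, network_union,
                      select_edges)
from .topology import TopologyReport, analyze, rank_hubs

__all__ = ["CorrelationNetworkModel", "CorrelationNetworkResults"]


class CorrelationNetworkModel:
    """A correlation network model of one samples x variables data matrix.

    Parameters
    ----------
    data : DataMatrix or pandas.DataFrame
        Samples in rows, variables in columns; NaN entries are missing.
    method : {"spearman", "pearson", "kendall"}
        Correlation type. Spearman is the default for metabolomics-scale
        data with missing values and non-normal marginals; use
        :meth:`normality_screen` to pick in a data-driven way.
    adjust_method : {"BH", "bonferroni", "none"}
        Multiple-testing adjustment across the v(v-1)/2 pair tests.
    min_pairs : int
        Minimum complete observations per pair; sparser pairs are undefined.

    Examples
    --------
    >>> import pandas as pd, numpy as np
    >>> rng = np.random.default_rng(0)
    >>> df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    >>> res = CorrelationNetworkModel(df, method="spearman").fit(r_min=0.7)
    >>> res.network.number_of_edges() >= 0
    True
    """

    def __init__(self, data, method: str = "spearman",
                 adjust_method: str = "BH", min_pairs: int = 4):
        if isinstance(data, pd.DataFrame):
            data = DataMatrix(values=data)
        if not isinstance(data, DataMatrix):
            raise TypeError("data must be a DataMatrix or pandas DataFrame")
        self.data = data
        self.method = method
        self.adjust_method = adjust_method
        self.min_pairs = min_pairs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition_label: str | None = None,
                       **kwargs) -> "CorrelationNetworkModel":
        return cls(DataMatrix(values=df, condition_label=condition_label),
                   **kwargs)

    @classmethod
    def from_csv(cls, path, orientation: str = "rows-are-samples",
                 condition_label: str | None = None,
                 **kwargs) -> "CorrelationNetworkModel":
        return cls(io_formats.read_data_matrix(path, orientation,
                                               condition_label), **kwargs)

    def normality_screen(self, alpha: float = 0.05):
        """Shapiro-Wilk screen; see :func:`corrnet.correlation.normality_screen`."""
        return normality_screen(self.data, alpha=alpha)

    def correlations(self) -> CorrelationResult:
        """The correlation/p-value matrices without edge selection."""
        return correlate(self.data, method=self.method,
                         adjust_method=self.adjust_method,
                         min_pairs=self.min_pairs)

    def fit(self, r_min: float = 0.7, p_max: float = 0.05,
            use_adjusted: bool = True,
            thresholds: Thresholds | None = None) -> "CorrelationNetworkResults":
        """Compute correlations, select significant edges, build the network.

        Defaults reproduce the common practice for small-sample profiling
        data: |r| >= 0.7 with BH-adjusted q < 0.05.
        """
        t = thresholds if thresholds is not None else Thresholds(
            r_min=r_min, p_max=p_max, use_adjusted=use_adjusted)
        corr = self.correlations()
        edges = select_edges(corr, t)
        net = build_network(edges)
        return CorrelationNetworkResults(model=self, correlations=corr,
                                         thresholds=t, edges=edges,
                                         network=net)


@dataclass
class CorrelationNetworkResults:
    """A fitted correlation network with its statistics and topology."""

    model: CorrelationNetworkModel
    correlations: CorrelationResult
    thresholds: Thresholds
    edges: EdgeTable
    network: nx.Graph
    _topology: TopologyReport | None = field(default=None, repr=False)

    @property
    def topology(self) -> TopologyReport:
        """Topology report of the fitted network (computed once, cached)."""
        if self._topology is None:
            self._topology = analyze(self.network)
        return self._topology

    @property
    def hubs(self) -> list:
        """Vertices ranked by betweenness (desc), degree (desc), label."""
        return rank_hubs(self.topology)

    def compare(self, other: "CorrelationNetworkResults | nx.Graph",
                op: str = "difference") -> nx.Graph:
        """Set operation between this fitted network and another.

        ``op`` is one of ``"union"``, ``"intersection"``, ``"difference"``
        (edges of self not in other). Edge identity is the unordered label
        pair; vertices left isolated are dropped.
        """
        b = other.network if isinstance(other, CorrelationNetworkResults) else other
        ops = {"union": network_union, "intersection": network_intersection,
               "difference": network_difference}
        if op not in ops:
            raise ValueError(f"unknown op: {op!r}")
        return ops[op](self.network, b)

    def save(self, prefix) -> None:
        """Write r/p tables, the edge table and the topology CSVs under a prefix."""
        prefix = str(prefix)
        io_formats.write_correlation_tables(self.correlations, prefix)
        io_formats.write_edge_table(self.edges, prefix + "edges.txt")
        self.topology.vertex_table.to_csv(prefix + "vertices.csv", index=False,
                                          float_format="%.6g")
        pd.DataFrame([self.topology.global_metrics]).to_csv(
            prefix + "global.csv", index=False, float_format="%.6g")

    def summary(self) -> str:
        """A printable summary in the spirit of a regression fit report."""
        g = self.topology.global_metrics
        cond = self.model.data.condition_label or "-"
        t = self.thresholds
        p_kind = "adjusted (q)" if t.use_adjusted else "raw"
        lines = [
            "        Correlation Network Results",
            "=" * 46,
            f"{'Condition:':<28}{cond}",
            f"{'Samples:':<28}{self.model.data.n_samples}",
            f"{'Variables:':<28}{self.model.data.n_variables}",
            f"{'Correlation method:':<28}{self.correlations.method}",
            f"{'Adjustment:':<28}{self.correlations.adjust_method}"
            f" over m={self.correlations.n_tests} pairs",
            f"{'Thresholds:':<28}|r| >= {t.r_min:g}, {p_kind} p < {t.p_max:g}",
            "-" * 46,
            f"{'Vertices:':<28}{g['vertex_count']}",
            f"{'Edges:':<28}{g['edge_count']}",
            f"{'Density:':<28}{g['density']:.3f}" if g["vertex_count"] >= 2
            else f"{'Density:':<28}undefined",
            f"{'Diameter:':<28}{g['diameter']}"
            f" ({g['connected_component_count']} component(s))",
            f"{'Transitivity:':<28}{g['transitivity']:.3f}",
            f"{'Avg shortest path:':<28}{g['average_shortest_path']:.3f}"
            if g["edge_count"] else f"{'Avg shortest path:':<28}undefined",
            "-" * 46,
            "Top hubs (betweenness / degree):",
        ]
        for _, row in self.topology.vertex_table.head(5).iterrows():
            lines.append(f"  {row['vertex']:<20}{row['betweenness']:.3f} / "
                         f"{int(row['degree'])}")
        lines.append("=" * 46)
        return "\n".join(lines)
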