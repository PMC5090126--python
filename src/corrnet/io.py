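"""File formats: data matrices, dual-triangle p-tables, edge tables, graph export.

Conventions
-----------
* Data matrices are CSV with one header row; an optional first label column
  is auto-detected (non-numeric first data cell). Empty cells, ``NA`` and
  ``NaN`` (case-insensitive) are missing.
* Correlation output is the classic pair of spreadsheet-ready files:
  ``<prefix>r_table.csv`` holds the full symmetric r matrix (unit diagonal)
  and ``<prefix>p_table.csv`` a single square matrix whose strictly-lower
  triangle stores the raw p-values and strictly-upper triangle the
  multiplicity-adjusted ones (diagonal 0).
* Edge tables are three-column tab-delimited text (source, target, r) with
  no header — directly importable by Cytoscape as a network table.
* Graphs export to SIF (interaction type ``corr``) or GraphML.

Numeric values are written with 6 significant digits.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationResult
from .datamatrix import DataMatrix
from .network import EdgeRecord, EdgeTable

__all__ = [
    "read_data_matrix",
    "write_data_matrix",
    "write_correlation_tables",
    "read_correlation_tables",
    "write_edge_table",
    "read_edge_table",
    "export_graph",
]

_NA_TOKENS = ["", "NA", "na", "Na", "nA", "NaN", "nan", "NAN"]
_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FMT % x


def read_data_matrix(path, orientation: str = "rows-are-samples",
                     condition_label: str | None = None) -> DataMatrix:
    """Read a delimited numeric matrix into samples x variables orientation.

    Parameters
    ----------
    path : path-like
        CSV file with one header row. If the first column is non-numeric it
        is taken as row labels; otherwise rows are numbered.
    orientation : {"rows-are-samples", "rows-are-variables"}
        How to interpret the file's rows; the returned matrix is always
        samples x variables.
    """
    if orientation not in ("rows-are-samples", "rows-are-variables"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, na_values=_NA_TOKENS, keep_default_na=False,
                     skipinitialspace=True)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"empty data matrix in {path}")
    first = df.iloc[:, 0]
    if not pd.api.types.is_numeric_dtype(first):
        labels = first.astype(str)
        if labels.duplicated().any():
            dup = labels[labels.duplicated()].iloc[0]
            raise ValueError(f"duplicate row id: {dup!r}")
        df = df.iloc[:, 1:]
        df.index = list(labels)
    cols = pd.Index(df.columns)
    if cols.duplicated().any():
        dup = cols[cols.duplicated()][0]
        raise ValueError(f"duplicate column id: {dup!r}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "rows-are-variables":
        df = df.T
    return DataMatrix(values=df, condition_label=condition_label)


def write_data_matrix(data: DataMatrix, path) -> None:
    """Write a samples x variables matrix as labelled CSV (NaN as empty cells)."""
    data.values.to_csv(path, index=True, index_label="sample",
                       float_format=_FMT, na_rep="")


def write_correlation_tables(result: CorrelationResult, prefix) -> tuple[Path, Path]:
    """Write the r matrix and the dual-triangle p matrix as two CSV files.

    ``<prefix>r_table.csv``: full symmetric r matrix with labels, diagonal 1.
    ``<prefix>p_table.csv``: square matrix with raw p-values in the
    strictly-lower triangle, adjusted p-values in the strictly-upper
    triangle, and 0 on the diagonal.

    Returns the two paths written.
    """
    result.validate()
    prefix = str(prefix)
    r_path = Path(prefix + "r_table.csv")
    p_path = Path(prefix + "p_table.csv")

    result.r.to_csv(r_path, index=True, index_label="", float_format=_FMT)

    ids = result.variable_ids
    p_raw = result.p_raw.to_numpy()
    p_adj = result.p_adj.to_numpy()
    dual = np.zeros_like(p_raw)
    il, jl = np.tril_indices(len(ids), k=-1)
    dual[il, jl] = p_raw[il, jl]          # lower triangle: raw
    dual[jl, il] = p_adj[jl, il]          # upper triangle: adjusted
    pd.DataFrame(dual, index=ids, columns=ids).to_csv(
        p_path, index=True, index_label="", float_format=_FMT
    )
    return r_path, p_path


def read_correlation_tables(r_path, p_path, method: str = "spearman",
                            adjust_method: str = "BH") -> CorrelationResult:
    """Reconstruct a correlation result from the r-table / dual-triangle p-table.

    The two files must carry identical variable labels. The r matrix must be
    symmetric; p-values must lie in [0, 1]. The pairwise sample counts are
    not stored in the files, so ``n_pairs`` is 0 in the reconstruction.
    """
    r = pd.read_csv(r_path, index_col=0, na_values=_NA_TOKENS,
                    keep_default_na=False)
    p = pd.read_csv(p_path, index_col=0, na_values=_NA_TOKENS,
                    keep_default_na=False)
    r.index = r.index.astype(str)
    r.columns = r.columns.astype(str)
    p.index = p.index.astype(str)
    p.columns = p.columns.astype(str)
    if list(r.index) != list(r.columns):
        raise ValueError("r table row/column labels differ")
    if list(p.index) != list(p.columns):
        raise ValueError("p table row/column labels differ")
    if list(r.index) != list(p.index):
        raise ValueError("label mismatch between r table and p table")
    rv = r.to_numpy(dtype=float)
    if not np.allclose(rv, rv.T, equal_nan=True, atol=1e-8):
        raise ValueError("r matrix in file is not symmetric")

    dual = p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(dual) < 0 or np.nanmax(dual) > 1:
            raise ValueError("p-values outside [0, 1]")
    v = dual.shape[0]
    p_raw = np.full((v, v), np.nan)
    p_adj = np.full((v, v), np.nan)
    il, jl = np.tril_indices(v, k=-1)
    p_raw[il, jl] = dual[il, jl]
    p_raw[jl, il] = dual[il, jl]
    p_adj[il, jl] = dual[jl, il]
    p_adj[jl, il] = dual[jl, il]
    np.fill_diagonal(p_raw, 0.0)
    np.fill_diagonal(p_adj, 0.0)

    ids = list(r.index)
    npairs = pd.DataFrame(np.zeros((v, v), dtype=int), index=ids, columns=ids)
    result = CorrelationResult(
        r=r,
        p_raw=pd.DataFrame(p_raw, index=ids, columns=ids),
        p_adj=pd.DataFrame(p_adj, index=ids, columns=ids),
        n_pairs=npairs,
        method=method,
        adjust_method=adjust_method,
    )
    result.validate()
    return result


def write_edge_table(edges: EdgeTable, path) -> Path:
    """Write edges as a three-column tab-delimited file (source, target, r).

    One row per unordered pair, no header. An empty table writes an empty
    file.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in edges:
            w.writerow([e.source, e.target, _fmt(e.r)])
    return path


def read_edge_table(path, header: bool = False) -> nx.Graph:
    """Read a tab-delimited edge table into an undirected simple graph.

    Each row needs at least two columns (source, target); a numeric third
    column becomes the edge ``weight``. Duplicate unordered pairs collapse
    to the first occurrence; self-loop rows are skipped with a warning.

    Parameters
    ----------
    header : bool
        Tolerate (and drop) one header line.
    """
    g = nx.Graph()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(row)}"
                )
            src, tgt = row[0].strip(), row[1].strip()
            if src == tgt:
                warnings.warn(
                    f"{path}:{lineno}: skipping self-loop on {src!r}",
                    UserWarning, stacklevel=2,
                )
                continue
            if g.has_edge(src, tgt):
                continue
            attrs = {}
            if len(row) >= 3:
                try:
                    attrs["weight"] = float(row[2])
                except ValueError:
                    pass
            g.add_edge(src, tgt, **attrs)
    return g


def graph_to_edge_table(g: nx.Graph) -> EdgeTable:
    """Convert a graph back to an edge table (weights become r; NaN if absent)."""
    table = EdgeTable()
    for u, v, d in g.edges(data=True):
        table.append(
            EdgeRecord(source=str(u), target=str(v),
                       r=float(d.get("weight", np.nan)),
                       p_raw=float(d.get("p_raw", np.nan)),
                       p_adj=float(d.get("p_adj", np.nan)))
        )
    return table


def export_graph(net: nx.Graph, fmt: str, path) -> Path:
    """Export a network as SIF or GraphML.

    SIF rows are ``source<TAB>corr<TAB>target``; isolated vertices are
    written as bare single-column rows, per the SIF convention.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for u, v in net.edges():
                w.writerow([u, "corr", v])
            for n in nx.isolates(net):
                w.writerow([n])
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r} (use SIF or GraphML)")
    return path
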