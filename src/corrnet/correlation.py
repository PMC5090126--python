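"""Pairwise correlation matrices with raw and multiplicity-adjusted p-values.

The correlation stage turns a samples x variables :class:`~corrnet.DataMatrix`
into three symmetric matrices: the correlation coefficients r, their two-sided
p-values, and the p-values adjusted for the m = v(v-1)/2 simultaneous tests.
Missing data are handled by pairwise-complete deletion: each pair (i, j) is
correlated on the samples where both variables are observed, and pairs with
fewer than ``min_pairs`` complete observations are marked undefined (NaN) so
they can never become edges downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamatrix import DataMatrix

__all__ = [
    "CorrelationResult",
    "NormalityScreen",
    "correlate",
    "adjust_pvalues",
    "normality_screen",
]

_METHODS = ("pearson", "spearman", "kendall")
_ADJUST = ("bonferroni", "BH", "none")


@dataclass
class CorrelationResult:
    """Symmetric r / p / adjusted-p matrices over one set of variables.

    All four matrices are pandas DataFrames indexed and columned by the
    variable ids. ``r`` has unit diagonal; ``p_raw`` and ``p_adj`` have zero
    diagonal; ``n_pairs`` counts complete observations per pair. Undefined
    pairs (too few complete observations, or zero variance) are NaN in ``r``,
    ``p_raw`` and ``p_adj``.
    """

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_pairs: pd.DataFrame
    method: str = "spearman"
    adjust_method: str = "BH"

    @property
    def variable_ids(self) -> list:
        return list(self.r.columns)

    @property
    def n_variables(self) -> int:
        return self.r.shape[1]

    @property
    def n_tests(self) -> int:
        """Number of unique off-diagonal pairs, m = v(v-1)/2."""
        v = self.n_variables
        return v * (v - 1) // 2

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        for name, m in (("r", self.r), ("p_raw", self.p_raw),
                        ("p_adj", self.p_adj), ("n_pairs", self.n_pairs)):
            if m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} matrix is not square")
            if list(m.index) != list(m.columns):
                raise ValueError(f"{name} row/column labels differ")
            a = m.to_numpy(dtype=float)
            if not np.allclose(a, a.T, equal_nan=True, atol=1e-8):
                raise ValueError(f"{name} matrix is not symmetric")
        rv = self.r.to_numpy(dtype=float)
        if np.nanmax(np.abs(rv)) > 1 + 1e-8:
            raise ValueError("|r| exceeds 1")
        for name, m in (("p_raw", self.p_raw), ("p_adj", self.p_adj)):
            a = m.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(a) < -1e-12 or np.nanmax(a) > 1 + 1e-12:
                    raise ValueError(f"{name} outside [0, 1]")


@dataclass
class NormalityScreen:
    """Per-variable Shapiro-Wilk results and the implied correlation method.

    ``table`` has one row per variable with columns ``W``, ``p`` and
    ``testable``; variables with fewer than 3 observations are untestable and
    are treated as non-normal. ``recommended_method`` is ``"pearson"`` only
    when every variable is testable and has p > alpha, otherwise
    ``"spearman"``.
    """

    table: pd.DataFrame
    alpha: float
    recommended_method: str


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Adjust a flat vector of p-values for multiple testing.

    Parameters
    ----------
    p_values : array-like
        Raw p-values over the unique tests, all in [0, 1]. NaNs are allowed
        and propagate to the output (the family size m counts only the
        non-NaN entries).
    method : {"bonferroni", "BH", "none"}
        ``bonferroni`` gives min(1, p*m); ``BH`` is the Benjamini-Hochberg
        step-up adjustment; ``none`` returns the input unchanged.

    Returns
    -------
    numpy.ndarray
        Adjusted p-values in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("bonferroni", "BH"):
        raise ValueError(f"unknown adjustment method: {method!r}")
    out = np.full_like(p, np.nan)
    if ok.sum() == 0:
        return out
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    out[ok] = multipletests(p[ok], method=sm_method)[1]
    return out


def _pair_stat(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """Correlation and two-sided p for one complete pair of vectors."""
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    # Kendall tau-b with the normal approximation
    tau, p = stats.kendalltau(x, y, method="asymptotic", variant="b")
    return float(tau), float(p)


def correlate(
    data: DataMatrix,
    method: str = "spearman",
    adjust_method: str = "BH",
    min_pairs: int = 4,
) -> CorrelationResult:
    """Compute the pairwise correlation, p-value and adjusted-p matrices.

    Each unordered variable pair is correlated on its pairwise-complete
    samples. Pairs with fewer than ``min_pairs`` complete observations, or
    with a constant variable on the complete samples, get NaN r and p and are
    excluded from the adjustment family. Adjusted p-values are computed over
    the m = v(v-1)/2 unique off-diagonal pairs (defined ones), never over the
    full v^2 matrix.

    Parameters
    ----------
    data : DataMatrix
    method : {"pearson", "spearman", "kendall"}
        Spearman (rank) correlation is the robust default for non-normal
        metabolomics data; run :func:`normality_screen` to choose.
    adjust_method : {"bonferroni", "BH", "none"}
    min_pairs : int
        Minimum number of complete observations for a pair to be defined.

    Returns
    -------
    CorrelationResult
    """
    if method not in _METHODS:
        raise ValueError(f"unknown correlation method: {method!r}")
    if adjust_method not in _ADJUST:
        raise ValueError(f"unknown adjustment method: {adjust_method!r}")
    if min_pairs < 3:
        raise ValueError("min_pairs must be at least 3")

    X = data.to_numpy()
    ids = data.variable_ids
    v = len(ids)
    obs = ~np.isnan(X)

    r = np.full((v, v), np.nan)
    p = np.full((v, v), np.nan)
    npairs = np.zeros((v, v), dtype=int)
    constant_vars: set = set()

    for i in range(v):
        npairs[i, i] = int(obs[:, i].sum())
        r[i, i] = 1.0
        p[i, i] = 0.0

    for i in range(v):
        for j in range(i + 1, v):
            both = obs[:, i] & obs[:, j]
            n = int(both.sum())
            npairs[i, j] = npairs[j, i] = n
            if n < min_pairs:
                continue
            x, y = X[both, i], X[both, j]
            if np.std(x) == 0:
                constant_vars.add(ids[i])
            if np.std(y) == 0:
                constant_vars.add(ids[j])
            rij, pij = _pair_stat(x, y, method)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij

    if constant_vars:
        warnings.warn(
            "constant variable(s) on complete pairs, correlations undefined: "
            + ", ".join(sorted(map(str, constant_vars))),
            UserWarning,
            stacklevel=2,
        )

    # adjust over the unique upper-triangle pairs only
    iu, ju = np.triu_indices(v, k=1)
    p_flat = p[iu, ju]
    p_adj_flat = adjust_pvalues(p_flat, adjust_method)
    p_adj = np.full((v, v), np.nan)
    p_adj[iu, ju] = p_adj_flat
    p_adj[ju, iu] = p_adj_flat
    np.fill_diagonal(p_adj, 0.0)

    def _df(a, dtype=float):
        return pd.DataFrame(a, index=ids, columns=ids).astype(dtype)

    return CorrelationResult(
        r=_df(r),
        p_raw=_df(p),
        p_adj=_df(p_adj),
        n_pairs=_df(npairs, int),
        method=method,
        adjust_method=adjust_method,
    )


def normality_screen(data: DataMatrix, alpha: float = 0.05) -> NormalityScreen:
    """Shapiro-Wilk normality test per variable, to choose the correlation type.

    Pearson correlation assumes (bivariate) normality; when any variable
    departs from normality at level ``alpha`` the rank-based Spearman
    correlation is recommended instead. Variables with fewer than 3 non-missing
    values cannot be tested and count as non-normal.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    all_normal = True
    for var in data.variable_ids:
        x = data.values[var].dropna().to_numpy()
        if x.size < 3 or np.std(x) == 0:
            rows.append({"variable": var, "W": np.nan, "p": np.nan,
                         "testable": False})
            all_normal = False
            continue
        W, pval = stats.shapiro(x)
        rows.append({"variable": var, "W": float(W), "p": float(pval),
                     "testable": True})
        if pval <= alpha:
            all_normal = False
    table = pd.DataFrame(rows).set_index("variable")
    return NormalityScreen(
        table=table,
        alpha=alpha,
        recommended_method="pearson" if all_normal else "spearman",
    )
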