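"""Signed weighted co-expression network construction.

Pipeline: Pearson correlation -> signed adjacency a_ij = ((1+cor_ij)/2)^beta
-> signed topological overlap. The soft power beta is chosen as the smallest
grid value whose network satisfies the scale-free topology criterion
(signed R^2 of the log-log degree fit >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "pairwise_correlation",
    "signed_adjacency",
    "signed_tom",
    "scale_free_fit",
    "pick_power",
    "connectivity",
    "NetworkModel",
    "ScaleFreeFit",
    "DEFAULT_POWERS",
]

DEFAULT_POWERS: tuple[int, ...] = tuple(range(1, 11)) + tuple(range(12, 51, 2))


def pairwise_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    """All gene-gene Pearson correlations; unit diagonal, entries in [-1, 1]."""
    values = expr.values.astype(float)
    if values.shape[1] < 3:
        raise ValueError("pairwise correlation requires at least 3 samples")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance gene(s): {bad}")
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.gene_ids, columns=expr.gene_ids)


def signed_adjacency(correlation: pd.DataFrame | np.ndarray, beta: float) -> pd.DataFrame:
    """Signed adjacency ((1 + cor)/2)^beta with unit diagonal."""
    if beta <= 0:
        raise ValueError(f"soft power must be positive, got {beta}")
    if isinstance(correlation, pd.DataFrame):
        index, cor = correlation.index, correlation.to_numpy(dtype=float)
    else:
        cor = np.asarray(correlation, dtype=float)
        index = pd.RangeIndex(cor.shape[0])
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=index, columns=index)


def connectivity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Whole-network connectivity: adjacency row sums excluding the diagonal."""
    adj = np.asarray(adjacency, dtype=float)
    return adj.sum(axis=1) - np.diag(adj)


def signed_tom(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap of a (signed) adjacency matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal. Requires a symmetric input.
    """
    if isinstance(adjacency, pd.DataFrame):
        index, adj = adjacency.index, adjacency.to_numpy(dtype=float)
    else:
        adj = np.asarray(adjacency, dtype=float)
        index = pd.RangeIndex(adj.shape[0])
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # u sums exclude i and j because diag(a) = 0
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=index, columns=index)


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit of a connectivity distribution at one power."""

    power: float
    r_squared_signed: float
    slope: float
    mean_k: float
    n_bins_used: int
    degenerate: bool = False  # fewer than 3 usable bins: R^2 trivially perfect


def scale_free_fit(k: np.ndarray, n_bins: int = 10, power: float = np.nan) -> ScaleFreeFit:
    """Log-log regression of the binned degree distribution.

    Connectivities are binned into ``n_bins`` equal-width bins, empty bins
    dropped, and log10(frequency) regressed on log10(mean k per bin). The
    returned statistic is R^2 signed by -sign(slope), so a decaying
    (power-law-like) distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("connectivity must be non-negative")
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    nonempty = counts > 0
    dk = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / k.size
    usable = dk > 0
    dk, freq = dk[usable], freq[usable]
    if dk.size < 2:
        raise ValueError("fewer than 2 usable bins; scale-free fit undefined")
    if dk.size == 2:
        # two points: the regression is numerically perfect; flag it
        slope = float(np.diff(np.log10(freq))[0] / np.diff(np.log10(dk))[0])
        return ScaleFreeFit(
            power=power,
            r_squared_signed=float(-np.sign(slope) * 1.0),
            slope=slope,
            mean_k=float(k.mean()),
            n_bins_used=2,
            degenerate=True,
        )
    fit = stats.linregress(np.log10(dk), np.log10(freq))
    r2 = fit.rvalue**2
    return ScaleFreeFit(
        power=power,
        r_squared_signed=float(-np.sign(fit.slope) * r2),
        slope=float(fit.slope),
        mean_k=float(k.mean()),
        n_bins_used=int(dk.size),
        degenerate=False,
    )


def pick_power(
    expr: ExpressionMatrix | None = None,
    powers=DEFAULT_POWERS,
    r2_threshold: float = 0.8,
    n_bins: int = 10,
    correlation: pd.DataFrame | None = None,
) -> tuple[float, pd.DataFrame, bool]:
    """Smallest soft power meeting the scale-free criterion.

    Returns ``(beta, fit_table, below_threshold)``. If no candidate reaches
    the threshold the power maximizing the signed R^2 is returned with the
    warning flag set. Either ``expr`` or a precomputed ``correlation`` must
    be given.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("power grid is empty")
    if correlation is None:
        if expr is None:
            raise ValueError("provide an expression matrix or a correlation matrix")
        correlation = pairwise_correlation(expr)
    rows = []
    for beta in powers:
        adj = signed_adjacency(correlation, beta)
        k = connectivity(adj)
        try:
            fit = scale_free_fit(k, n_bins=n_bins, power=beta)
        except ValueError:
            fit = ScaleFreeFit(beta, np.nan, np.nan, float(np.mean(k)), 0, True)
        rows.append(fit)
    table = pd.DataFrame(
        {
            "power": [f.power for f in rows],
            "r_squared_signed": [f.r_squared_signed for f in rows],
            "slope": [f.slope for f in rows],
            "mean_k": [f.mean_k for f in rows],
            "n_bins_used": [f.n_bins_used for f in rows],
            "degenerate": [f.degenerate for f in rows],
        }
    )
    qualifying = table[table["r_squared_signed"] >= r2_threshold]
    if len(qualifying):
        beta = float(qualifying.iloc[0]["power"])
        return beta, table, False
    best = table["r_squared_signed"].idxmax()
    return float(table.loc[best, "power"]), table, True


@dataclass
class NetworkModel:
    """Correlation, signed adjacency, signed TOM and connectivity together."""

    correlation: pd.DataFrame
    beta: float
    adjacency: pd.DataFrame = field(init=False, default=None)
    tom: pd.DataFrame = field(init=False, default=None)
    k: np.ndarray = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.adjacency = signed_adjacency(self.correlation, self.beta)
        self.tom = signed_tom(self.adjacency)
        self.k = connectivity(self.adjacency)

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, beta: float) -> "NetworkModel":
        return cls(correlation=pairwise_correlation(expr), beta=beta)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.correlation.index)
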