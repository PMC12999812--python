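"""Gene filtering, negative-value handling, size factors and the VST.

The order of operations downstream code relies on is: clamp/round negatives
(artifacts of upstream batch correction) -> expression filter -> median-of-
ratios size factors -> variance-stabilizing transform. Correlation-based
network math assumes the transformed values have an approximately
mean-independent variance, which is the contract the VST here provides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import CountMatrix, ExpressionMatrix, FilterReport

__all__ = [
    "clamp_negatives",
    "filter_genes",
    "size_factors",
    "fit_dispersion_trend",
    "vst",
    "DispersionTrend",
]


def clamp_negatives(counts: CountMatrix) -> tuple[CountMatrix, int, float]:
    """Set negative entries to zero and round to integers.

    Returns the clamped matrix plus the negative-entry count and fraction,
    both computed on the *input* matrix before clamping.
    """
    values = counts.values.astype(float)
    n_negative = int(np.count_nonzero(values < 0))
    negative_fraction = n_negative / values.size if values.size else 0.0
    clamped = np.rint(np.clip(values, 0, None)).astype(np.int64)
    out = CountMatrix.from_arrays(clamped, counts.gene_ids, counts.sample_ids)
    return out, n_negative, negative_fraction


def filter_genes(
    counts: CountMatrix,
    min_count: float = 15,
    min_fraction: float = 0.75,
    n_negative_values: int = 0,
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes with >= ``min_count`` counts in >= ``min_fraction`` of samples.

    Both thresholds are inclusive. ``n_negative_values`` (from a preceding
    :func:`clamp_negatives`) is carried into the report so the negative
    fraction is reported on the full input matrix.
    """
    values = counts.values
    if np.any(values < 0):
        raise ValueError("filter_genes expects non-negative counts; run clamp_negatives first")
    frac_ok = (values >= min_count).mean(axis=1)
    keep = frac_ok >= min_fraction
    if not keep.any():
        raise ValueError(
            "no gene passes the expression filter "
            f"(min_count={min_count}, min_fraction={min_fraction}); relax the thresholds"
        )
    filtered = CountMatrix(counts.frame.loc[keep])
    report = FilterReport(
        n_input_genes=counts.n_genes,
        n_retained=filtered.n_genes,
        n_negative_values=n_negative_values,
        negative_fraction=(
            n_negative_values / (counts.n_genes * counts.n_samples)
            if counts.n_genes and counts.n_samples
            else 0.0
        ),
        min_count=min_count,
        min_fraction=min_fraction,
    )
    return filtered, report


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    Reference genes are those with nonzero counts in every sample; for each
    sample the factor is the median ratio of its counts to the per-gene
    geometric mean over those reference genes.
    """
    values = counts.values.astype(float)
    reference = np.all(values > 0, axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; size factors are undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = values[reference]
    geomean = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    return np.median(ref / geomean, axis=0)


@dataclass
class DispersionTrend:
    """Parametric mean-dispersion trend alpha(mu) = a1/mu + alpha0."""

    a1: float
    alpha0: float

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a1 / mu + self.alpha0


def _gene_dispersions(q: np.ndarray, xim: float) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments per-gene dispersion estimates on normalized counts."""
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - xim * mu) / mu**2
    ok = (mu > 0) & np.isfinite(disp) & (disp > 1e-8)
    return mu[ok], disp[ok]


def fit_dispersion_trend(counts: CountMatrix, factors: np.ndarray) -> DispersionTrend:
    """Fit alpha(mu) = a1/mu + alpha0 by nonnegative least squares."""
    q = counts.values.astype(float) / np.asarray(factors, dtype=float)
    xim = float(np.mean(1.0 / np.asarray(factors, dtype=float)))
    mu, disp = _gene_dispersions(q, xim)
    if mu.size < 2:
        raise ValueError("too few genes with positive dispersion to fit a trend")
    design = np.column_stack([1.0 / mu, np.ones_like(mu)])
    coef, _ = nnls(design, disp)
    return DispersionTrend(a1=float(coef[0]), alpha0=float(coef[1]))


def _vst_closed_form(q: np.ndarray, trend: DispersionTrend) -> np.ndarray:
    """Closed-form NB variance stabilizer for the parametric trend.

    Exact integral of 1/sqrt(v(q)) with v(q) = (1+a1)q + alpha0 q^2, rescaled
    to behave as log2(q) + const for large q.
    """
    a1, alpha0 = trend.a1, trend.alpha0
    inner = alpha0 * q * (1.0 + a1 + alpha0 * q)
    arg = (1.0 + a1 + 2.0 * alpha0 * q + 2.0 * np.sqrt(inner)) / (4.0 * alpha0)
    return np.log2(arg)


def vst(
    counts: CountMatrix,
    factors: np.ndarray,
    method: str = "parametric",
    trend: DispersionTrend | None = None,
) -> ExpressionMatrix:
    """Variance-stabilizing transform of normalized counts.

    ``method='parametric'`` fits the mean-dispersion trend and applies the
    closed-form stabilizer; ``method='log'`` is the log2(q + 1) fallback.
    Monotone per sample either way, and approaches log2(count/factor) + const
    for large counts.
    """
    values = counts.values.astype(float)
    if np.any(values < 0):
        raise ValueError("vst expects non-negative counts")
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,) or np.any(factors <= 0):
        raise ValueError("factors must be positive, one per sample")
    q = values / factors
    if method == "log":
        transformed = np.log2(q + 1.0)
    elif method == "parametric":
        if trend is None:
            try:
                trend = fit_dispersion_trend(counts, factors)
            except ValueError as err:
                warnings.warn(
                    f"dispersion trend unfittable ({err}); falling back to log2(q+1)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                trend = None
        if trend is None or trend.alpha0 <= 1e-10:
            if trend is not None:
                warnings.warn(
                    "asymptotic dispersion ~ 0; falling back to log2(q+1)",
                    RuntimeWarning,
                    stacklevel=2,
                )
            transformed = np.log2(q + 1.0)
        else:
            transformed = _vst_closed_form(q, trend)
    else:
        raise ValueError(f"unknown vst method {method!r}")
    return ExpressionMatrix(
        pd.DataFrame(transformed, index=counts.gene_ids, columns=counts.sample_ids)
    )
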