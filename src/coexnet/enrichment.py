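"""Over-representation analysis of module gene sets against GMT collections.

The statistic is the hypergeometric upper tail P(X >= k) (one-sided Fisher
exact), with Benjamini-Hochberg control across the sets tested for one
module. The universe defaults to the genes surviving the expression filter;
changing the universe changes every p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

__all__ = ["hypergeom_upper_tail", "bh_adjust", "enrich_module"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for overlap of a size-n draw with a size-K set in a size-N urn."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_module(
    module_genes,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    min_set_size: int = 5,
    max_set_size: int = 2000,
) -> pd.DataFrame:
    """One-module ORA over all sets in the collection.

    Sets are intersected with the universe first and skipped outside the
    [min_set_size, max_set_size] guardrails. Rows are sorted by adjusted then
    raw p-value, ties by set name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    outside = module - universe
    if outside:
        raise ValueError(
            f"{len(outside)} module gene(s) missing from the universe, "
            f"e.g. {sorted(outside)[:5]}"
        )
    N, n = len(universe), len(module)
    rows = []
    for name, members in collection.sets.items():
        in_universe = [g for g in members if g in universe]
        K = len(in_universe)
        if K == 0 or not (min_set_size <= K <= max_set_size):
            continue
        overlap = sorted(module.intersection(in_universe))
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_upper_tail(k, K, n, N),
                "overlap_genes": overlap,
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_raw", "overlap_genes"]
    )
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_raw"].to_numpy())
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    result["significant"] = result["p_adjusted"] < alpha
    return result.sort_values(
        ["p_adjusted", "p_raw", "set_name"], kind="stable"
    ).reset_index(drop=True)
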