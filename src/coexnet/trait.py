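"""Module-trait association and gene significance.

A binary case/control trait is encoded 0/1 and treated as numeric, so the
Pearson correlation with an eigengene is the point-biserial correlation.
Significance uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) with
n-2 degrees of freedom, two-tailed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleTable
from .modules import GREY

__all__ = [
    "cor_pvalue",
    "module_trait_table",
    "gene_significance",
    "mm_gs_agreement",
]


def cor_pvalue(r: float, n: int) -> float:
    """Two-tailed Student-t p-value of a Pearson correlation at sample size n."""
    if n < 3:
        raise ValueError(f"correlation p-value requires n >= 3, got n={n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0  # exact fit; flagged by callers
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_table(
    eigengenes: pd.DataFrame, samples: SampleTable
) -> pd.DataFrame:
    """Per-module trait correlation table: r, p, n, df, flags.

    ``eigengenes`` is samples x modules. Sample ids must align with the
    sample table; mismatches raise with an explicit listing. A grey column,
    if present, is kept but flagged.
    """
    trait = samples.aligned_trait(list(eigengenes.index)).to_numpy(dtype=float)
    if trait.std() == 0:
        raise ValueError("trait has no variation across the provided samples")
    rows = []
    n = len(eigengenes.index)
    for module in eigengenes.columns:
        me = eigengenes[module].to_numpy(dtype=float)
        r = float(np.corrcoef(me, trait)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        rows.append(
            {
                "module": module,
                "trait": "trait",
                "r": r,
                "p": cor_pvalue(r, n),
                "n": n,
                "df": n - 2,
                "exact_fit": abs(r) == 1.0,
                "is_grey": module == GREY,
            }
        )
    return pd.DataFrame(rows).set_index("module")


def gene_significance(expr: ExpressionMatrix, samples: SampleTable) -> pd.Series:
    """GS per gene: absolute Pearson correlation of expression with the trait.

    Zero-variance genes get NaN (flagged missing) rather than an error, so a
    single degenerate gene does not abort a whole-matrix scan.
    """
    trait = samples.aligned_trait(expr.sample_ids).to_numpy(dtype=float)
    x = expr.values.astype(float)
    sd = x.std(axis=1)
    tc = trait - trait.mean()
    tnorm = np.linalg.norm(tc)
    if tnorm == 0:
        raise ValueError("trait has no variation across the provided samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = x - x.mean(axis=1, keepdims=True)
        cor = (xc @ tc) / (np.linalg.norm(xc, axis=1) * tnorm)
    gs = np.abs(np.clip(cor, -1.0, 1.0))
    gs[sd == 0] = np.nan
    return pd.Series(gs, index=expr.gene_ids, name="GS")


def mm_gs_agreement(
    kme_column: pd.Series, gs: pd.Series, members
) -> tuple[float, float]:
    """Correlation between |kME| and gene significance over module members."""
    members = list(members)
    if len(members) < 3:
        raise ValueError("module membership / gene significance agreement needs >= 3 genes")
    mm = kme_column.loc[members].abs().to_numpy(dtype=float)
    sig = gs.loc[members].to_numpy(dtype=float)
    if np.isnan(sig).any():
        raise ValueError("gene significance undefined (NaN) for some member genes")
    r = float(np.clip(np.corrcoef(mm, sig)[0, 1], -1.0, 1.0))
    return r, cor_pvalue(r, len(members))
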