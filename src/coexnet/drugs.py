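"""Drug-gene interaction scoring and therapeutic-target prioritization.

Per gene, a composite drug-gene interaction (DGI) score combines a base
score from the number of targeting drugs (weight 0.4), an interaction-type
quality bonus for high-value types such as inhibitors/antagonists (0.3) and
a source-reliability bonus for expert-curated databases (0.3). The priority
score is 0.7 * DGI + 0.3 * druggable-genome status, and tier labels follow
fixed score intervals (upper-inclusive above zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DrugCatalog, DrugRecord

__all__ = [
    "ScoreConfig",
    "dgi_score",
    "priority_score",
    "classify",
    "rank_genes",
    "feature_similarity_network",
    "DGI_TIERS",
    "PRIORITY_TIERS",
]

# (upper bound, label); intervals are [0, b1], (b1, b2], (b2, 1]
DGI_TIERS = ((0.2, "Low"), (0.5, "Moderate"), (1.0, "High"))
PRIORITY_TIERS = ((0.3, "Low"), (0.6, "Medium"), (1.0, "High"))


@dataclass
class ScoreConfig:
    """Tunable pieces of the composite scoring scheme.

    The 0.4/0.3/0.3 component weights and the 0.7/0.3 priority combination
    are fixed by the scheme; the functional forms of the components are
    configurable: the drug count saturates at ``max_drugs``, and the two
    bonuses are the fraction of claims with a high-value interaction type /
    from an expert-curated source.
    """

    base_weight: float = 0.4
    type_weight: float = 0.3
    source_weight: float = 0.3
    dgi_weight: float = 0.7
    status_weight: float = 0.3
    max_drugs: int = 5
    high_value_types: frozenset[str] = frozenset({"inhibitor", "antagonist"})
    curated_sources: frozenset[str] = frozenset({"DrugBank", "ChEMBL"})

    def __post_init__(self) -> None:
        if not np.isclose(self.base_weight + self.type_weight + self.source_weight, 1.0):
            raise ValueError("component weights must sum to 1")
        if not np.isclose(self.dgi_weight + self.status_weight, 1.0):
            raise ValueError("priority weights must sum to 1")
        self.high_value_types = frozenset(t.lower() for t in self.high_value_types)
        self.curated_sources = frozenset(s.lower() for s in self.curated_sources)


DEFAULT_CONFIG = ScoreConfig()


def dgi_score(record: DrugRecord, config: ScoreConfig = DEFAULT_CONFIG) -> float:
    """Composite drug-gene interaction score in [0, 1]; 0 for no interactions."""
    if record.interaction_count == 0:
        return 0.0
    base = min(record.n_drugs, config.max_drugs) / config.max_drugs
    types = [t.lower() for t in record.interaction_types]
    type_bonus = sum(t in config.high_value_types for t in types) / len(types)
    sources = [s.lower() for s in record.sources]
    source_bonus = sum(s in config.curated_sources for s in sources) / len(sources)
    return (
        config.base_weight * base
        + config.type_weight * type_bonus
        + config.source_weight * source_bonus
    )


def priority_score(
    dgi: float, druggable_status: int, config: ScoreConfig = DEFAULT_CONFIG
) -> float:
    """Priority = 0.7 * DGI score + 0.3 * druggable-genome status (exact)."""
    if not 0.0 <= dgi <= 1.0:
        raise ValueError(f"dgi score out of [0, 1]: {dgi}")
    if druggable_status not in (0, 1, False, True):
        raise ValueError(f"druggable status must be 0 or 1, got {druggable_status!r}")
    return config.dgi_weight * dgi + config.status_weight * int(druggable_status)


def classify(score: float, kind: str) -> str:
    """Tier label for a score; ``kind`` is 'dgi' or 'priority'."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score out of [0, 1]: {score}")
    tiers = {"dgi": DGI_TIERS, "priority": PRIORITY_TIERS}.get(kind)
    if tiers is None:
        raise ValueError(f"kind must be 'dgi' or 'priority', got {kind!r}")
    for bound, label in tiers:
        if score <= bound:
            return label
    return tiers[-1][1]  # unreachable for valid scores


def rank_genes(
    catalog: DrugCatalog, gene_list, config: ScoreConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Prioritization table over ``gene_list``, sorted by priority then DGI.

    Genes absent from the catalog get the empty record (all-zero scores,
    Low tiers). Ties beyond the scores break by gene identifier, so the
    ordering is invariant to catalog row order.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list is empty")
    rows = []
    for gene in gene_list:
        record = catalog.get(gene)
        dgi = dgi_score(record, config)
        status = int(record.druggable_genome_member)
        priority = priority_score(dgi, status, config)
        rows.append(
            {
                "gene": gene,
                "n_drugs": record.n_drugs,
                "n_interactions": record.interaction_count,
                "interaction_types": ";".join(record.interaction_types),
                "sources": ";".join(record.sources),
                "druggable_genome_member": bool(status),
                "dgi_score": dgi,
                "priority_score": priority,
                "dgi_tier": classify(dgi, "dgi"),
                "priority_tier": classify(priority, "priority"),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["priority_score", "dgi_score", "gene"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)


_FEATURES = ["priority_score", "dgi_score", "n_interactions", "n_drugs"]


def feature_similarity_network(
    table: pd.DataFrame, top_n: int = 20, threshold: float = 0.8
) -> pd.DataFrame:
    """Edges between top-ranked genes with similar interaction profiles.

    Feature vectors (priority score, DGI score, claim count, drug count) are
    min-max normalized over the top-n genes; an edge joins two genes when the
    Pearson correlation of their feature vectors exceeds the threshold.
    Isolated genes are simply absent from the edge list (nodes are the table).
    """
    if top_n < 2:
        raise ValueError("top_n must be at least 2")
    top = table.head(top_n)
    feats = top[_FEATURES].to_numpy(dtype=float)
    spans = feats.max(axis=0) - feats.min(axis=0)
    constant = spans == 0
    if constant.any():
        dropped = [f for f, c in zip(_FEATURES, constant) if c]
        warnings.warn(
            f"dropping constant feature column(s): {dropped}", RuntimeWarning, stacklevel=2
        )
        feats = feats[:, ~constant]
        spans = spans[~constant]
    if feats.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features; similarity undefined")
    norm = (feats - feats.min(axis=0)) / spans
    genes = top["gene"].tolist()
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = norm[i], norm[j]
            if a.std() == 0 or b.std() == 0:
                cor = 1.0 if np.allclose(a, b) else 0.0
            else:
                cor = float(np.corrcoef(a, b)[0, 1])
            if cor > threshold:
                edges.append({"source": genes[i], "target": genes[j], "similarity": cor})
    return pd.DataFrame(edges, columns=["source", "target", "similarity"])
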