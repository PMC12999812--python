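"""Cytoscape-compatible exports: thresholded edge lists and pathway-annotated
node tables for a module of interest.

Edges are pairwise Pearson correlations among the displayed genes that exceed
a quantile threshold (default the third quartile of that subnetwork's
correlations), tagged as within- or cross-module with respect to the original
(pre-merge) module labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .modules import ModulePartition

__all__ = ["edge_list", "node_annotation", "write_edge_list", "write_sif"]


def edge_list(
    expr: ExpressionMatrix,
    genes,
    quantile: float = 0.75,
    module_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlation edges among ``genes`` above the given quantile threshold.

    The threshold is the ``quantile`` of the upper-triangle correlation values
    of the displayed subset (strictly exceeded). Pairs are deduplicated with
    source < target lexically.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("edge list requires at least 2 genes")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie strictly in (0, 1), got {quantile}")
    sub = expr.frame.loc[genes].to_numpy(dtype=float)
    cor = np.corrcoef(sub)
    iu, ju = np.triu_indices(len(genes), k=1)
    values = cor[iu, ju]
    threshold = float(np.quantile(values, quantile))
    keep = values > threshold
    rows = []
    for i, j, w in zip(iu[keep], ju[keep], values[keep]):
        a, b = genes[i], genes[j]
        source, target = (a, b) if a < b else (b, a)
        if module_labels is not None:
            origin = (
                "within_module"
                if module_labels.get(a) == module_labels.get(b)
                else "cross_module"
            )
        else:
            origin = "within_module"
        rows.append({"source": source, "target": target, "weight": float(w), "origin": origin})
    frame = pd.DataFrame(rows, columns=["source", "target", "weight", "origin"])
    return frame.sort_values(["source", "target"], kind="stable").reset_index(drop=True)


def node_annotation(
    partition: ModulePartition,
    enrichment_results: pd.DataFrame,
    selected_sets,
    target_modules,
    hub_stats: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene pathway membership flags for the target module(s).

    ``selected_sets`` must be a subset of the sets present in the enrichment
    results; flags come from each set's overlap_genes. Genes in at least one
    selected set are marked annotated. ``hub_stats`` (kWithin) adds a 1-based
    hub rank within the target gene set, ties broken lexically.
    """
    selected_sets = list(selected_sets)
    available = set(enrichment_results["set_name"])
    unknown = [s for s in selected_sets if s not in available]
    if unknown:
        raise KeyError(f"selected set(s) absent from enrichment results: {unknown}")
    overlap = {
        row.set_name: set(row.overlap_genes)
        for row in enrichment_results.itertuples()
        if row.set_name in selected_sets
    }
    if isinstance(target_modules, str):
        target_modules = [target_modules]
    genes: list[str] = []
    for module in target_modules:
        genes.extend(partition.members(module))
    rows = []
    for gene in genes:
        flags = {s: gene in overlap[s] for s in selected_sets}
        rows.append(
            {
                "gene": gene,
                "module": partition.labels[gene],
                **flags,
                "annotated": any(flags.values()),
            }
        )
    frame = pd.DataFrame(rows)
    if hub_stats is not None:
        ranked = sorted(genes, key=lambda g: (-hub_stats.get(g, -np.inf), g))
        rank = {g: i + 1 for i, g in enumerate(ranked)}
        frame["hub_rank"] = frame["gene"].map(rank)
    return frame


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path, interaction: str = "co") -> None:
    """Simple interaction format: source TAB interaction TAB target."""
    with open(path, "w", encoding="utf-8") as handle:
        for row in edges.itertuples():
            handle.write(f"{row.source}\t{interaction}\t{row.target}\n")
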