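"""Model/Results front-end tying the pipeline stages together.

``CoexpressionModel`` holds the (variance-stabilized) expression matrix and
sample metadata; ``fit`` runs soft-power selection, signed network and TOM
construction, dendrogram clustering, dynamic tree cut and automatic module
merging, and returns a ``CoexpressionResults`` carrying the partition,
eigengenes, connectivity statistics and the module-trait association table,
with enrichment, prioritization and export hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import drugs as _drugs
from . import enrichment as _enrichment
from . import export as _export
from .containers import (
    CountMatrix,
    DrugCatalog,
    ExpressionMatrix,
    FilterReport,
    GeneSetCollection,
    SampleTable,
)
from .modules import (
    ConnectivityStats,
    Eigengene,
    ModulePartition,
    auto_merge,
    cluster_genes,
    compute_eigengene,
    connectivity_stats,
    dynamic_tree_cut,
    eigengene_matrix,
    manual_merge,
    reassign_by_kme,
)
from .network import DEFAULT_POWERS, NetworkModel, pairwise_correlation, pick_power
from .preprocess import clamp_negatives, filter_genes, size_factors, vst
from .trait import gene_significance, module_trait_table

__all__ = ["CoexpressionModel", "CoexpressionResults"]


class CoexpressionModel:
    """Signed weighted co-expression network model of an expression matrix."""

    def __init__(self, expr: ExpressionMatrix, samples: SampleTable | None = None):
        self.expr = expr
        self.samples = samples
        self.filter_report: FilterReport | None = None

    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        samples: SampleTable | None = None,
        min_count: float = 15,
        min_fraction: float = 0.75,
        vst_method: str = "parametric",
    ) -> "CoexpressionModel":
        """Preprocess raw counts: clamp negatives, filter, size factors, VST."""
        clamped, n_neg, _ = clamp_negatives(counts)
        filtered, report = filter_genes(
            clamped, min_count=min_count, min_fraction=min_fraction, n_negative_values=n_neg
        )
        factors = size_factors(filtered)
        expr = vst(filtered, factors, method=vst_method)
        model = cls(expr, samples)
        model.filter_report = report
        return model

    def fit(
        self,
        power: float | None = None,
        powers=DEFAULT_POWERS,
        r2_threshold: float = 0.8,
        min_module_size: int = 30,
        deep_split: int = 2,
        merge_cut_height: float = 0.25,
        reassign_min_kme: float | None = None,
    ) -> "CoexpressionResults":
        correlation = pairwise_correlation(self.expr)
        power_table = None
        power_warning = False
        if power is None:
            power, power_table, power_warning = pick_power(
                correlation=correlation, powers=powers, r2_threshold=r2_threshold
            )
        net = NetworkModel(correlation=correlation, beta=power)
        dendrogram = cluster_genes(net.tom)
        partition = dynamic_tree_cut(
            dendrogram, net.tom, min_module_size=min_module_size, deep_split=deep_split
        )
        if reassign_min_kme is not None:
            partition = reassign_by_kme(partition, self.expr, reassign_min_kme)
        partition = auto_merge(partition, self.expr, merge_cut_height)
        return CoexpressionResults(
            model=self,
            network=net,
            dendrogram=dendrogram,
            partition=partition,
            power_table=power_table,
            power_below_threshold=power_warning,
        )


@dataclass
class CoexpressionResults:
    """Fitted network, module partition and downstream statistics."""

    model: CoexpressionModel
    network: NetworkModel
    dendrogram: np.ndarray
    partition: ModulePartition
    power_table: pd.DataFrame | None = None
    power_below_threshold: bool = False

    def __post_init__(self) -> None:
        self._refresh()

    def _refresh(self) -> None:
        self.eigengenes, self._eigengene_entries = eigengene_matrix(
            self.model.expr, self.partition
        )
        self.connectivity = connectivity_stats(
            self.model.expr, self.network.adjacency, self.partition, self.eigengenes
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def expr(self) -> ExpressionMatrix:
        return self.model.expr

    def eigengene(self, module: str) -> Eigengene:
        return self._eigengene_entries[module]

    @property
    def kme(self) -> pd.DataFrame:
        return self.connectivity.kme

    @property
    def kwithin(self) -> pd.Series:
        return self.connectivity.kwithin

    def hub_genes(self, module: str, n: int = 30) -> list[str]:
        return self.connectivity.hub_genes(self.partition, module, n)

    # -- trait association -----------------------------------------------------
    def module_trait(self, samples: SampleTable | None = None) -> pd.DataFrame:
        samples = samples or self.model.samples
        if samples is None:
            raise ValueError("no sample table attached to the model")
        return module_trait_table(self.eigengenes, samples)

    def gene_significance(self, samples: SampleTable | None = None) -> pd.Series:
        samples = samples or self.model.samples
        if samples is None:
            raise ValueError("no sample table attached to the model")
        return gene_significance(self.model.expr, samples)

    # -- module merging --------------------------------------------------------
    def merge_modules(self, module_names, new_name: str) -> "CoexpressionResults":
        """Rationale-driven manual merge; returns a new results object."""
        merged = manual_merge(self.partition, module_names, new_name)
        return CoexpressionResults(
            model=self.model,
            network=self.network,
            dendrogram=self.dendrogram,
            partition=merged,
            power_table=self.power_table,
            power_below_threshold=self.power_below_threshold,
        )

    # -- downstream analyses ---------------------------------------------------
    def enrich(
        self, module: str, collection: GeneSetCollection, alpha: float = 0.05, **kwargs
    ) -> pd.DataFrame:
        """ORA of one module against a collection; universe = filtered genes."""
        return _enrichment.enrich_module(
            self.partition.members(module),
            collection,
            universe=self.model.expr.gene_ids,
            alpha=alpha,
            **kwargs,
        )

    def prioritize(
        self, module: str, catalog: DrugCatalog, config=_drugs.DEFAULT_CONFIG
    ) -> pd.DataFrame:
        return _drugs.rank_genes(catalog, self.partition.members(module), config)

    def export_edges(
        self, module: str, quantile: float = 0.75, original_labels: pd.Series | None = None
    ) -> pd.DataFrame:
        labels = original_labels if original_labels is not None else self.partition.labels
        return _export.edge_list(
            self.model.expr, self.partition.members(module), quantile, labels
        )

    # -- reporting -------------------------------------------------------------
    def summary(self, samples: SampleTable | None = None) -> str:
        """Human-readable module summary table."""
        sizes = self.partition.module_sizes()
        trait = None
        try:
            trait = self.module_trait(samples)
        except ValueError:
            pass
        lines = [
            "Co-expression network results",
            f"  genes: {len(self.partition.gene_ids)}   "
            f"samples: {self.model.expr.n_samples}   soft power: {self.network.beta:g}",
        ]
        if self.power_below_threshold:
            lines.append("  warning: no power reached the scale-free R^2 threshold")
        header = f"  {'module':<14}{'size':>6}{'varExpl':>9}"
        if trait is not None:
            header += f"{'r(trait)':>10}{'p':>10}"
        lines.append(header)
        for module, size in sizes.items():
            if module in self.eigengenes.columns:
                ve = f"{self.eigengene(module).variance_explained:.3f}"
            else:
                ve = "-"
            row = f"  {module:<14}{size:>6}{ve:>9}"
            if trait is not None and module in trait.index:
                row += f"{trait.loc[module, 'r']:>10.3f}{trait.loc[module, 'p']:>10.3g}"
            elif trait is not None:
                row += f"{'-':>10}{'-':>10}"
            lines.append(row)
        return "\n".join(lines)

    def plot_module_trait(self, samples: SampleTable | None = None, ax=None):
        """Bar plot of module-trait correlations (requires matplotlib)."""
        import matplotlib.pyplot as plt

        trait = self.module_trait(samples)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        trait["r"].plot.bar(ax=ax, color="steelblue")
        ax.axhline(0, color="black", lw=0.8)
        ax.set_ylabel("eigengene-trait Pearson r")
        for i, (_, row) in enumerate(trait.iterrows()):
            ax.text(i, row["r"], f"p={row['p']:.3f}", ha="center", fontsize=7)
        return ax
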