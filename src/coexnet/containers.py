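"""Core in-memory containers shared across the pipeline.

All matrices are gene-by-sample pandas DataFrames wrapped in thin dataclasses
that enforce the identifier invariants (uniqueness, alignment) once, so the
science modules never have to re-validate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleTable",
    "GeneSetCollection",
    "DrugRecord",
    "DrugCatalog",
    "FilterReport",
]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifier(s): {dupes}")


@dataclass
class _GeneBySample:
    """Gene x sample numeric matrix with unique, ordered identifiers."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        _check_unique(self.frame.index, "gene")
        _check_unique(self.frame.columns, "sample")
        self.frame.index = self.frame.index.astype(str)
        self.frame.columns = self.frame.columns.astype(str)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    @classmethod
    def from_arrays(cls, values, gene_ids, sample_ids):
        values = np.asarray(values)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))


@dataclass
class CountMatrix(_GeneBySample):
    """Raw (or batch-corrected) counts; may contain negatives on input."""


@dataclass
class ExpressionMatrix(_GeneBySample):
    """Variance-stabilized expression used for all correlation math."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.frame.to_numpy(dtype=float))):
            raise ValueError("ExpressionMatrix must contain only finite values")


@dataclass
class SampleTable:
    """Per-sample metadata with a strictly binary trait (0=control, 1=case)."""

    frame: pd.DataFrame  # indexed by sample_id, column "trait" plus covariates

    def __post_init__(self) -> None:
        if "trait" not in self.frame.columns:
            raise ValueError("sample table requires a 'trait' column")
        _check_unique(self.frame.index, "sample")
        self.frame.index = self.frame.index.astype(str)
        trait = self.frame["trait"]
        bad = ~trait.isin([0, 1])
        if bad.any():
            raise ValueError(
                f"trait must be binary 0/1; offending samples: {list(self.frame.index[bad])}"
            )
        self.frame["trait"] = trait.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def trait(self) -> pd.Series:
        return self.frame["trait"]

    def aligned_trait(self, sample_ids) -> pd.Series:
        """Trait vector re-ordered to ``sample_ids``; error lists mismatches."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples absent from sample table: {missing}")
        return self.frame.loc[list(sample_ids), "trait"]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. from a GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


@dataclass
class DrugRecord:
    """Aggregated drug-interaction claims for one gene."""

    gene: str
    drug_names: list[str] = field(default_factory=list)
    interaction_types: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)
    druggable_genome_member: bool = False

    @property
    def n_drugs(self) -> int:
        return len(set(self.drug_names))

    @property
    def interaction_count(self) -> int:
        # one row per claim; a drug may carry several claims
        return len(self.drug_names)


@dataclass
class DrugCatalog:
    """Per-gene aggregation of a flat drug-gene interaction claim table."""

    records: dict[str, DrugRecord]

    def get(self, gene: str) -> DrugRecord:
        """Record for ``gene``; an empty record if the gene is un-annotated."""
        return self.records.get(gene, DrugRecord(gene=gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterReport:
    """Bookkeeping for negative-value clamping and expression filtering."""

    n_input_genes: int
    n_retained: int
    n_negative_values: int
    negative_fraction: float
    min_count: float
    min_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_retained <= self.n_input_genes:
            raise ValueError("0 <= n_retained <= n_input_genes violated")

    @property
    def negative_percent(self) -> str:
        """Negative fraction as a two-decimal percentage string (e.g. '0.17')."""
        return f"{100.0 * self.negative_fraction:.2f}"

    def to_dict(self) -> dict:
        return {
            "n_input_genes": self.n_input_genes,
            "n_retained": self.n_retained,
            "n_negative_values": self.n_negative_values,
            "negative_fraction": self.negative_fraction,
            "negative_percent": self.negative_percent,
            "min_count": self.min_count,
            "min_fraction": self.min_fraction,
        }
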