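"""Readers and writers for every on-disk format the pipeline touches.

No science lives here. Dialects: UTF-8 text, TAB-delimited by default with
CSV auto-detected from the ``.csv`` extension; GMT in the Broad dialect
(name TAB description TAB member...); the drug catalog as a flat per-claim
TSV with columns gene, drug, interaction_type, source, druggable_genome.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .containers import (
    CountMatrix,
    DrugCatalog,
    DrugRecord,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_gmt",
    "write_gmt",
    "read_drug_catalog",
    "write_drug_catalog",
]

_TRUE = {"true", "1", "yes", "t", "y"}


def _delimiter_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_matrix(path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    idx = frame.index
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier(s) in {path.name}: {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric cell in {path.name} at gene {gene!r}, sample {col!r}: "
            f"{frame.loc[gene, col]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"missing value(s) in {path.name}")
    return numeric


def read_counts(path, delimiter: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix (first column gene ids, header samples)."""
    return CountMatrix(_read_matrix(path, delimiter))


def write_counts(counts: CountMatrix, path, delimiter: str | None = None) -> None:
    counts.frame.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="gene")


def read_expression(path, delimiter: str | None = None) -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix(path, delimiter))


def write_expression(expr: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    expr.frame.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="gene")


def read_samples(path, delimiter: str | None = None) -> SampleTable:
    """Read a sample table with columns sample_id, trait (plus free covariates)."""
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep)
    if "sample_id" not in frame.columns:
        raise ValueError("sample table requires a 'sample_id' column")
    frame = frame.set_index("sample_id")
    return SampleTable(frame)


def write_samples(samples: SampleTable, path, delimiter: str | None = None) -> None:
    samples.frame.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{os.fspath(path)}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"{os.fspath(path)}:{lineno}: duplicate set name {name!r}")
            # dedup preserving first-seen order
            members = list(dict.fromkeys(m for m in members if m))
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


_CATALOG_COLUMNS = ["gene", "drug", "interaction_type", "source", "druggable_genome"]


def read_drug_catalog(path, delimiter: str | None = None) -> DrugCatalog:
    """Aggregate a flat per-claim drug-gene interaction table into a catalog.

    One input row is one claim; the same drug may appear in several rows for a
    gene (distinct sources), so distinct-drug count and claim count differ.
    The druggable-genome flag is OR-ed over a gene's rows.
    """
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in _CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"drug catalog missing mandatory column(s): {missing}")
    records: dict[str, DrugRecord] = {}
    for gene, group in frame.groupby("gene", sort=True):
        records[gene] = DrugRecord(
            gene=gene,
            drug_names=sorted(group["drug"]),
            interaction_types=sorted(group["interaction_type"]),
            sources=sorted(group["source"]),
            druggable_genome_member=bool(
                group["druggable_genome"].str.strip().str.lower().isin(_TRUE).any()
            ),
        )
    return DrugCatalog(records=records)


def write_drug_catalog(frame: pd.DataFrame, path, delimiter: str | None = None) -> None:
    """Write a flat per-claim drug catalog table (columns as read_drug_catalog)."""
    missing = [c for c in _CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"drug catalog frame missing column(s): {missing}")
    frame.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)
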