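"""Seeded generators for every input the pipeline consumes, with ground truth.

The expression generator emulates a whole-blood bulk RNA-seq cohort: a binary
case/control trait with fixed margins (default 62 cases / 29 controls),
negative-binomial counts with a parametric mean-dispersion trend
alpha(mu) = a1/mu + alpha0, per-sample library-size factors, K planted
co-expression modules driven by latent factors (optionally weakly correlated
with the trait), a large unstructured background, and a small fraction of
negative entries mimicking batch-correction artifacts in lowly expressed
genes. The ground truth fully determines the joint distribution and is
returned (and serializable) alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, DrugCatalog, DrugRecord, GeneSetCollection, SampleTable
from .drugs import DEFAULT_CONFIG, ScoreConfig, classify, dgi_score, priority_score

__all__ = [
    "ModuleSpec",
    "GeneratorTruth",
    "generate_expression",
    "generate_gene_sets",
    "generate_drug_catalog",
    "cohort_module_spec",
    "COHORT_N_GENES",
]

BACKGROUND = "background"

# Desk-scale benchmark mirroring the study's shape: ~2,000 genes, five modules
# whose sizes echo the real ones, ~60% unstructured background, n = 62 + 29,
# and two modules weakly correlated with the trait.
COHORT_N_GENES = 2000


def cohort_module_spec() -> list["ModuleSpec"]:
    return [
        ModuleSpec(size=350, within_cor=0.50, trait_rho=0.0),
        ModuleSpec(size=170, within_cor=0.45, trait_rho=0.0),
        ModuleSpec(size=145, within_cor=0.45, trait_rho=0.21),
        ModuleSpec(size=40, within_cor=0.55, trait_rho=0.19),
        ModuleSpec(size=35, within_cor=0.55, trait_rho=0.0),
    ]


@dataclass
class ModuleSpec:
    """One planted module: size, latent within-module correlation, trait link."""

    size: int
    within_cor: float
    trait_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be positive")
        if not 0.0 <= self.within_cor <= 1.0:
            raise ValueError("within_cor must lie in [0, 1]")
        if not abs(self.trait_rho) < 1.0:
            raise ValueError("|trait_rho| must be < 1")


@dataclass
class GeneratorTruth:
    """Everything needed to reconstruct what was planted."""

    seed: int
    module_labels: dict[str, str]  # gene -> planted module name or "background"
    factors: dict[str, list[float]]  # module -> latent factor over samples
    trait_rho: dict[str, float]
    within_cor: dict[str, float]
    a1: float
    alpha0: float
    size_factors: list[float]
    sample_ids: list[str]
    planted_sets: dict[str, str] = field(default_factory=dict)  # set name -> module
    tier_design: dict[str, dict] = field(default_factory=dict)  # gene -> planted tiers

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.module_labels.items() if m == module]

    def modules(self) -> list[str]:
        seen = dict.fromkeys(m for m in self.module_labels.values() if m != BACKGROUND)
        return list(seen)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(asdict(self), handle, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneratorTruth":
        with open(path, encoding="utf-8") as handle:
            return cls(**json.load(handle))


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _factor_with_correlation(rng, trait: np.ndarray, rho: float) -> np.ndarray:
    """Unit-variance latent factor with exact in-sample correlation rho to trait."""
    zt = _standardize(trait.astype(float))
    noise = rng.standard_normal(trait.size)
    resid = noise - (noise @ zt) / (zt @ zt) * zt
    return rho * zt + np.sqrt(1.0 - rho**2) * _standardize(resid)


def generate_expression(
    n_genes: int,
    n_cases: int = 62,
    n_controls: int = 29,
    module_spec: list[ModuleSpec] | None = None,
    seed: int = 1234,
    baseline_log2_range: tuple[float, float] = (8.0, 12.0),
    low_expression_fraction: float = 0.10,
    signal_sd: float = 0.8,
    a1: float = 1.0,
    alpha0: float = 0.01,
    libsize_sd: float = 0.25,
    negative_fraction: float = 0.0017,
) -> tuple[CountMatrix, SampleTable, GeneratorTruth]:
    """Simulate counts with planted module structure and record the truth.

    ``module_spec`` defaults to the cohort-like five-module design. Genes not
    covered by the module sizes form the unstructured background; a
    ``low_expression_fraction`` of background genes get very low baselines so
    the expression filter removes them (these rows also host the planted
    negative batch-correction artifacts).
    """
    if module_spec is None:
        module_spec = cohort_module_spec()
    total_module = sum(m.size for m in module_spec)
    if total_module > n_genes:
        raise ValueError(
            f"module sizes sum to {total_module} > n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    n_samples = n_cases + n_controls
    sample_ids = [f"case_{i + 1:03d}" for i in range(n_cases)] + [
        f"ctrl_{i + 1:03d}" for i in range(n_controls)
    ]
    trait = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    labels = np.array([BACKGROUND] * n_genes, dtype=object)
    signal = np.empty((n_genes, n_samples))
    factors: dict[str, list[float]] = {}
    rho_truth: dict[str, float] = {}
    cor_truth: dict[str, float] = {}
    start = 0
    for idx, spec in enumerate(module_spec, start=1):
        name = f"planted_{idx}"
        members = slice(start, start + spec.size)
        labels[members] = name
        f = _factor_with_correlation(rng, trait, spec.trait_rho)
        loading = np.sqrt(spec.within_cor)
        noise = rng.standard_normal((spec.size, n_samples))
        signal[members] = loading * f + np.sqrt(1.0 - spec.within_cor) * noise
        factors[name] = f.tolist()
        rho_truth[name] = spec.trait_rho
        cor_truth[name] = spec.within_cor
        start += spec.size
    n_background = n_genes - total_module
    signal[start:] = rng.standard_normal((n_background, n_samples))

    lo, hi = baseline_log2_range
    baselines = rng.uniform(lo, hi, size=n_genes)
    n_low = int(round(low_expression_fraction * n_background))
    low_rows = rng.choice(np.arange(start, n_genes), size=n_low, replace=False) if n_low else []
    baselines[low_rows] = rng.uniform(-1.0, 3.0, size=n_low)

    size_fac = np.exp(rng.normal(0.0, libsize_sd, size=n_samples))
    size_fac /= np.exp(np.mean(np.log(size_fac)))  # geometric mean 1

    mu = size_fac * 2.0 ** (baselines[:, None] + signal_sd * signal)
    alpha = a1 / mu + alpha0
    r = 1.0 / alpha
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(float)

    n_entries = counts.size
    n_neg = int(round(negative_fraction * n_entries))
    if n_neg:
        candidate_rows = np.asarray(low_rows if len(low_rows) else np.arange(n_genes))
        flat = (
            candidate_rows[:, None] * n_samples + np.arange(n_samples)[None, :]
        ).ravel()
        chosen = rng.choice(flat, size=min(n_neg, flat.size), replace=False)
        counts.ravel()[chosen] = -rng.integers(1, 10, size=chosen.size).astype(float)

    count_matrix = CountMatrix.from_arrays(counts, gene_ids, sample_ids)
    sample_table = SampleTable(pd.DataFrame({"trait": trait}, index=sample_ids))
    truth = GeneratorTruth(
        seed=seed,
        module_labels=dict(zip(gene_ids, labels)),
        factors=factors,
        trait_rho=rho_truth,
        within_cor=cor_truth,
        a1=a1,
        alpha0=alpha0,
        size_factors=size_fac.tolist(),
        sample_ids=sample_ids,
    )
    return count_matrix, sample_table, truth


def generate_gene_sets(
    truth: GeneratorTruth,
    n_decoy_sets: int = 20,
    contamination: float = 0.1,
    max_planted_size: int = 30,
    decoy_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> GeneSetCollection:
    """One planted set per true module plus random decoy sets.

    A planted set is a random subset of its module's genes with a stated
    contamination rate of background-drawn members; decoys are uniform draws
    from all genes. Planted set names are recorded in the truth object.
    """
    rng = np.random.default_rng(seed)
    all_genes = np.array(list(truth.module_labels))
    background = np.array(truth.module_genes(BACKGROUND))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for module in truth.modules():
        members = np.array(truth.module_genes(module))
        size = min(max_planted_size, members.size)
        picked = list(rng.choice(members, size=size, replace=False))
        n_contam = int(round(contamination * size))
        if n_contam and background.size:
            contam = rng.choice(background, size=n_contam, replace=False)
            picked[:n_contam] = list(contam)
        name = f"planted_set_{module}"
        sets[name] = sorted(picked)
        descriptions[name] = f"synthetic set planted over {module}"
        truth.planted_sets[name] = module
    lo, hi = decoy_size_range
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"decoy_{i + 1:03d}"
        sets[name] = sorted(rng.choice(all_genes, size=size, replace=False))
        descriptions[name] = "synthetic decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


_TIER_TEMPLATES = {
    # dgi tier -> (n_drugs options, claim builder)
    "High": ([4, 5], lambda nd: [("inhibitor", "DrugBank")] * nd),
    "Moderate": ([2], lambda nd: [("inhibitor", "DrugBank"), ("binder", "OtherDB")]),
    "Low": ([1], lambda nd: [("binder", "OtherDB")]),
}


def generate_drug_catalog(
    genes,
    tier_design: dict[str, tuple[str, bool]],
    seed: int = 0,
    config: ScoreConfig = DEFAULT_CONFIG,
    truth: GeneratorTruth | None = None,
) -> tuple[DrugCatalog, pd.DataFrame, dict[str, dict]]:
    """Per-claim catalog whose configured scores land in designed tiers.

    ``tier_design`` maps gene -> (dgi tier, druggable flag); genes not listed
    get no rows at all (the majority, as in real drug-interaction exports).
    Returns the aggregated catalog, the flat claim table (writable via
    :func:`coexnet.io.write_drug_catalog`), and the planted truth: per gene
    the designed DGI tier, druggable status, and the implied priority tier.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    unknown = [g for g in tier_design if g not in set(genes)]
    if unknown:
        raise ValueError(f"tier design names gene(s) outside the gene list: {unknown}")
    rows = []
    records: dict[str, DrugRecord] = {}
    planted: dict[str, dict] = {}
    for gene in genes:
        if gene not in tier_design:
            continue
        tier, druggable = tier_design[gene]
        if tier not in _TIER_TEMPLATES:
            raise ValueError(f"unknown dgi tier {tier!r} for gene {gene}")
        options, claims_for = _TIER_TEMPLATES[tier]
        n_drugs = int(rng.choice(options))
        claims = claims_for(n_drugs)
        drug_names = [f"{gene}_cmpd{i + 1}" for i in range(n_drugs)]
        # one claim per drug for High; templates for lower tiers are fixed-size
        claim_drugs = drug_names[: len(claims)]
        record = DrugRecord(
            gene=gene,
            drug_names=sorted(claim_drugs),
            interaction_types=sorted(t for t, _ in claims),
            sources=sorted(s for _, s in claims),
            druggable_genome_member=bool(druggable),
        )
        score = dgi_score(record, config)
        if classify(score, "dgi") != tier:
            raise ValueError(
                f"dgi tier {tier!r} unreachable for gene {gene} under the scoring "
                f"config (template scores {score:.3f})"
            )
        records[gene] = record
        for drug, (itype, source) in zip(claim_drugs, claims):
            rows.append(
                {
                    "gene": gene,
                    "drug": drug,
                    "interaction_type": itype,
                    "source": source,
                    "druggable_genome": str(druggable).lower(),
                }
            )
        priority = priority_score(score, int(druggable), config)
        planted[gene] = {
            "dgi_tier": tier,
            "druggable": bool(druggable),
            "priority_tier": classify(priority, "priority"),
        }
    claim_table = pd.DataFrame(
        rows, columns=["gene", "drug", "interaction_type", "source", "druggable_genome"]
    )
    if truth is not None:
        truth.tier_design = planted
    return DrugCatalog(records=records), claim_table, planted
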