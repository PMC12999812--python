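# coexnet

Signed weighted gene co-expression network analysis for case/control bulk
RNA-seq cohorts, with module–trait association, over-representation
enrichment, and drug–gene interaction prioritization of candidate modules.

## Who this is for

Transcriptomics researchers who want the classic WGCNA-style workflow —
expression filtering, variance-stabilizing transformation, signed network
and topological overlap construction, dynamic tree cut module detection,
eigengene–trait correlation, hypergeometric ORA — together with a composite
druggability scoring scheme for translating a disease-associated module into
ranked therapeutic target candidates, all as a tested Python library with a
seeded synthetic-data generator for validation.

## The model

Given a variance-stabilized expression matrix, genes are connected by the
**signed adjacency** `a_ij = ((1 + cor_ij)/2)^β`, with the soft power β
chosen as the smallest grid value whose connectivity distribution meets the
scale-free topology criterion (signed R² ≥ 0.8). The **signed topological
overlap**

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

defines a dissimilarity `1 − TOM` that is clustered by average linkage;
modules are cohesive dendrogram branches of at least `min_module_size` genes
(unassigned genes form the reserved *grey* module). Each module is summarized
by its **eigengene** (first principal component of the gene-standardized
member submatrix), correlated with the binary trait via the point-biserial
Pearson r and the Student-t transform `t = r·√(n−2)/√(1−r²)`. Modules whose
eigengene dissimilarity falls below 0.25 are merged automatically; a manual,
rationale-driven merge is also supported. Module gene sets are tested for
over-representation against user-supplied GMT collections (hypergeometric
upper tail, Benjamini–Hochberg). Finally, genes are scored for druggability:

    dgi      = 0.4·base(n_drugs) + 0.3·type_bonus + 0.3·source_bonus
    priority = 0.7·dgi + 0.3·druggable_genome_status

with tier labels Low/Moderate/High (DGI: 0.2, 0.5 boundaries) and
Low/Medium/High priority (0.3, 0.6 boundaries).

## Worked example

```python
from coexnet.synthetic import generate_expression
from coexnet.model import CoexpressionModel

counts, samples, truth = generate_expression(2000, seed=1234)  # 62 cases / 29 controls
model = CoexpressionModel.from_counts(counts, samples)         # clamp, filter, VST
results = model.fit()                                          # β pick, TOM, modules
print(results.summary(samples))
```

```
Co-expression network results
  genes: 1874   samples: 91   soft power: 5
  module          size  varExpl  r(trait)         p
  grey            1130        -         -         -
  turquoise        354    0.394    -0.028     0.789
  blue             170    0.409    -0.027     0.798
  brown            145    0.424     0.198    0.0593
  yellow            40    0.564     0.158     0.134
  green             35    0.563    -0.002     0.982
```

The generator planted five modules (sizes 350/170/145/40/35) in a 2,000-gene
background, two of them weakly correlated with the binary trait
(ρ = 0.21 and 0.19). The fit recovers all five — with a large grey set of
unassigned background genes — and the two trait-linked modules surface with
r ≈ 0.20 and 0.16 at n = 91, the weak-association regime this design
stresses. Downstream:

```python
merged = results.merge_modules(["brown", "yellow"], "yb")   # rationale-driven union
table  = merged.module_trait(samples)                       # r, p per module
enr    = merged.enrich("yb", my_gmt_collection)             # ORA vs filtered universe
ranked = merged.prioritize("yb", drug_catalog)              # tiers + priority scores
edges  = merged.export_edges("yb", quantile=0.75)           # Cytoscape edge list
```

The same pipeline runs from the shell:

```sh
coexnet run-all --simulate --seed 1234 --outdir out/
```

writing every intermediate (expression, power-fit table, module assignments,
trait table, per-module enrichment, priority table, edge list) plus a
manifest with the config hash and per-file content hashes.

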