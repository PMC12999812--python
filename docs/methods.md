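# Methods

## Pipeline and assumptions

The package analyzes a gene × sample count matrix from a case/control bulk
RNA-seq cohort. The count matrix may be the output of an upstream batch
correction, which can leave a small number of negative entries; batch
correction itself is out of scope here — the pipeline only repairs its
artifacts (negatives are set to zero and values rounded back to integers,
since the downstream variance model assumes counts). Processing order is:
clamp/round → expression filter → size factors → variance-stabilizing
transform (VST) → correlation network. The filter (≥ `min_count` in ≥
`min_fraction` of samples, both inclusive; defaults 15 and 0.75) removes the
lowly expressed genes in which such artifacts concentrate and which cannot
support stable pairwise correlations.

**Normalization and VST.** Size factors are classic median-of-ratios:
reference genes are those expressed in every sample; the factor of sample
*j* is the median of its ratios to the per-gene geometric means. The median
is taken on the ratio scale (not the log scale), which matters only for
even reference-gene counts. The VST fits per-gene method-of-moments
dispersions on normalized counts, regresses the parametric trend
α(μ) = a₁/μ + α₀ by nonnegative least squares, and applies the closed-form
stabilizer

    vst(q) = log2( (1 + a₁ + 2α₀q + 2√(α₀q(1 + a₁ + α₀q))) / (4α₀) ),

the exact integral of 1/√v(q) for v(q) = (1+a₁)q + α₀q², rescaled to behave
as log2(q) + const for large q. Its delta-method standard deviation is
√α₀/ln 2 at every mean, which is the property the correlation network needs:
without it, mean-dependent variance masquerades as co-expression strength.
A `log2(q+1)` fallback exists behind a flag and is used automatically when
the trend is unfittable (e.g. all-zero input) or α₀ ≈ 0. Note that on data
with this dispersion trend the per-gene SD of `log2(q+1)` *decreases* with
the mean in the filtered-count regime (CV² = (1+a₁)/μ + α₀); the VST's
advantage is a near-zero mean–SD slope, not a sign flip, and that is what
the variance-flatness test asserts.

**Network.** Pearson correlations over samples (≥3 required; zero-variance
genes are an error), signed adjacency `((1+cor)/2)^β`, unit diagonal. The
soft power is chosen from the grid 1–10, 12–50 step 2 as the smallest value
whose signed scale-free fit R² reaches 0.8; if none qualifies the
best-fitting power is returned with a warning flag rather than an error.
The scale-free statistic bins connectivities into 10 equal-width bins
(empty bins dropped; a two-bin fit is numerically perfect and flagged
degenerate) and regresses log-frequency on log-mean-connectivity, signing R²
by the negated slope sign. Equal-count binning was considered and rejected:
it makes the per-bin frequency constant by construction, degenerating the
regression. The signed TOM uses the standard shared-neighbor formula with a
zeroed diagonal inside the matrix product; the whole matrix is computed in
one block (desk-scale gene counts fit comfortably in memory, and block-wise
processing changes results only through pre-clustering).

**Module detection.** Average-linkage clustering of `1 − TOM`
(scipy's implementation; an O(n³) naive agglomerator serves as the test
oracle). Branch decomposition is adaptive: candidate cut heights across the
merge-height range are scanned, and the cut maximizing (number of
qualifying branches, total branch gap) is kept, ties toward the lowest cut.
A branch qualifies if it has ≥ `min_module_size` (default 30) genes and its
own root merge sits at least a minimum gap below the cut — the gap is what
separates genuine co-expression branches from the shallow clumps an
unstructured dissimilarity produces near the tree root (measured on
pure-noise simulations, random ≥30-gene clumps never exceed ~0.002 of the
height range; planted modules hold gaps an order of magnitude larger).
`deep_split` ∈ {0..4} maps to that gap fraction (0.02, 0.01, 0.005, 0.0025,
0.001; default 2), so higher values accept shallower branches. A fixed cut
at a constant fraction of the height range (the textbook "tree" variant)
was tried first and proved brittle: on weak-signal networks the merge
heights compress into a few percent of the range and a constant fraction
lands arbitrarily. An optional second stage (`reassign_by_kme`, off by
default) pulls grey genes into the module whose eigengene they correlate
with at ≥ a threshold, mirroring the PAM-like reassignment of the reference
tree-cut implementation.

**Eigengenes and merging.** The module eigengene is the leading right
singular vector of the per-gene z-scored member submatrix, unit norm over
samples, oriented so its mean correlation with member genes is ≥ 0 (residual
ties resolve toward the first member gene); variance explained is
σ₁²/Σσ². Automatic merging clusters eigengenes by average linkage on
`1 − cor` and unions clusters below `merge_cut_height` (default 0.25,
strictly below — a zero height is a no-op), recomputing eigengenes until a
fixpoint; grey never merges; a merged cluster keeps its largest
constituent's name. Manual merges union explicitly named modules under a new
name and recompute the eigengene from the union (not an average of the old
eigengenes). Modules are named by size-ranked conventional colors
(turquoise, blue, brown, …), ties broken by first-gene position.

**Trait association.** The binary trait is coded 0/1 and used numerically,
so eigengene–trait Pearson correlation is the point-biserial coefficient;
p-values come from the exact t transform with n−2 df, two-tailed. No
multiple-testing correction is applied to the module–trait matrix by
default (the module count is small and the raw values are the quantities of
interest); BH is available where many sets are tested. Gene significance is
|cor(expression, trait)|; zero-variance genes get NaN rather than an error.

**Enrichment.** Hypergeometric upper tail P(X ≥ k) per set, sets intersected
with the universe first and kept within [5, 2000] members, BH across the
sets tested for one module, significance at adjusted p < 0.05. The universe
is the filter-surviving gene list — changing it changes every p-value, so
the choice is part of the contract. BH is delegated to statsmodels'
step-up implementation behind the `bh_adjust` surface.

**Drug–gene prioritization.** Only the 0.4/0.3/0.3 component weights and
the 0.7/0.3 priority combination are fixed by the scheme; the component
functional forms are this package's documented reconstruction: the drug
count saturates at 5 (`min(n_drugs, 5)/5`), the type bonus is the fraction
of claims whose type is in the configured high-value set (default
inhibitor/antagonist), and the source bonus is the fraction of claims from
the configured curated-source set (default DrugBank/ChEMBL). All three are
config-overridable; monotone and bounded by construction. Druggable-genome
status is binary. Tier intervals overlap at their printed endpoints, so the
implementation fixes an upper-inclusive convention: DGI [0, 0.2], (0.2,
0.5], (0.5, 1]; priority [0, 0.3], (0.3, 0.6], (0.6, 1] — consistent with
the published exemplar labels (0.39 Moderate; 0.573 Medium; 0.608 and 0.769
High). The feature-similarity network min-max normalizes (priority, DGI,
claim count, drug count) over the top-n genes, drops constant columns with
a warning, and links gene pairs whose feature-vector correlation strictly
exceeds the threshold; isolated genes simply emit no edges.

**Exports.** Edge lists take all pairwise correlations among the displayed
genes, threshold strictly above the chosen quantile of that subnetwork's
own upper-triangle values (default the third quartile), deduplicate with
source < target, and tag edges within/cross module against a caller-chosen
labelling (typically the pre-merge labels). Node tables flag membership in
selected enriched pathways from the recorded overlap genes and rank hubs by
kWithin, ties lexical.

## Synthetic data: what it emulates, and what it does not

The generator mimics the study design: 62 cases / 29 controls, negative
binomial counts with trend α(μ) = a₁/μ + α₀, lognormal library-size factors,
K latent-factor modules, a large unstructured background, and a ~0.17%
sprinkle of negative entries confined to a low-expression stratum (10% of
background genes with log2-baselines in [−1, 3], which the expression filter
removes, matching where such artifacts concentrate in real cohorts). The cohort-like
profile is 2,000 genes with module sizes 350/170/145/40/35 (~60%
background) and two modules trait-correlated at ρ = 0.21 and 0.19 —
deliberately the weak-association regime. Latent factors are constructed
with *exact* in-sample correlation to the trait (noise residualized against
the trait and recombined), so recovery bias measures the estimation
pipeline, not factor-sampling noise. Defaults chosen once as realistic for a
whole-blood cohort: baselines log2-uniform on [8, 12], per-gene biological
signal SD 0.8 on the log2 scale, a₁ = 1, α₀ = 0.01, library-size log-SD
0.25.

Known attenuation: median-of-ratios size factors partially absorb a shared
module factor when a sizable fraction of genes carry it (~10%+), lowering
measured within-module correlations below the planted value by several
hundredths. This is a property of the estimator — it occurs on real data
with global co-regulation too — so the generator's correlation contract is
verified on the true planted library sizes.

What passing these tests does **not** show about real data: the background
here is exactly independent noise (no correlated cell-type composition
axes, no unmodelled batch structure), modules are single-factor and
disjoint, dispersion follows the parametric trend exactly, and gene
identifiers carry no annotation structure. Scale-free power selection on
this generator typically lands at β ≈ 4–10, below the value a real cohort's
pervasive weak correlation structure demands; conclusions about a specific
β are data-dependent and not portable.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and diagonals forced to 1 before
  powering; TOM is symmetrized and clipped to [0, 1].
- |r| = 1 returns p = 0 with an exact-fit flag rather than an error.
- Eigengene computation excludes zero-variance members with a warning and
  errors only if none remain; orientation tie-breaks are deterministic.
- `min_module_size` > gene count warns and returns all-grey; an all-equal
  connectivity vector or an all-equal merge-height tree is rejected or
  returns all-grey respectively.
- Hub rankings and gene orderings break ties lexically everywhere, making
  every output invariant to input row order.
- All stochastic code takes an explicit integer seed (default 1234) through
  `numpy.random.default_rng`; the fitting path itself is deterministic.

## Limitations

- Unsigned/hybrid network types and biweight midcorrelation are not
  implemented; neither are module-preservation statistics or consensus
  networks across datasets.
- Exact output equality with the reference R tree-cut implementation is not
  a goal; planted-structure recovery is the validated surface.
- The drug catalog is a flat per-claim file; no live database queries, and
  printed composite scores from any external catalog snapshot are not
  claimed reproducible from raw records — only the downstream 0.7/0.3 combination
  and tier assignment are.
- Covariate-adjusted trait association (age/sex) is out of scope; the trait
  must be strictly binary.
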