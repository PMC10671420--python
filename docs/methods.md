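# Methods

## Scope and model

`pmscoex` implements a weighted gene co-expression network analysis
(WGCNA) pipeline specialized for phenotype-driven candidate-gene
prioritization in the 22q13.2–q13.33 region. The statistical model
underlying every stage is the standard co-expression assumption: genes
sharing regulation load on common latent expression programs, so modules
of the correlation network are candidate functional units, and an
unannotated region gene that sits centrally in a module enriched for a
phenotype's known genes is "guilty by association".

## Preprocessing

Input is a genes × samples matrix in RPKM units (plain TSV/CSV, or the
BrainSpan dialect of expression + row metadata + column metadata).
Duplicate gene rows collapse to the highest-mean row. Genes with zero
total RPKM are removed, values are log2(RPKM + 1) transformed (tracked
by an explicit unit state; transforming twice is an error), and genes
with mean expression < 0.3 RPKM are filtered. The filter uses the mean
on the RPKM scale, computed before the transform and carried along; the
boundary is kept (a gene at exactly 0.3 stays), since the rule filters
strictly below the threshold. Per-gene descriptive statistics go to a QC
report but drive no decision other than the mean filter. Missing values
are a hard error — RPKM matrices are dense, and silent imputation would
be worse than failing. Sample outliers (Euclidean average-linkage
clustering; singletons above the 0.95-quantile merge height) are flagged
in the log, never removed.

## Network construction

Similarity is the absolute Pearson correlation of log-scale profiles
(`unsigned_abs`, the default); a signed variant (1 + cor)/2 is available
by configuration for users who want anti-correlated genes kept apart.
Soft thresholding raises the similarity element-wise to an integer power
β. For each candidate β (default 1..20) the connectivity
k_i = Σ_{j≠i} a_ij is summarized by a scale-free fit: connectivities are
binned into 10 equal-width bins, log10 relative frequency is regressed
on log10 bin center over non-empty bins, and R² is signed by −sign(slope)
so that only a decreasing (power-law-like) tail counts as a good fit.
The chosen β is the smallest candidate with signed R² ≥ 0.8 (the target
is configurable); if none qualifies, a configured fallback (default 9)
is used and flagged prominently. Constant connectivity returns a
degenerate flag rather than a fit.

The adjacency is transformed to the unsigned topological overlap matrix

    T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,

with diagonal 1, and D = 1 − T is the clustering dissimilarity. All
matrices are dense; a guard refuses more than 20,000 genes up front
rather than thrashing memory.

## Module detection

Genes are clustered by average linkage (UPGMA) on D. Two cut methods are
provided:

- **static** — connected components below a fixed height; components
  smaller than `min_module_size` go grey.
- **dynamic_branch** (default) — a recursive gap-based branch cut. A
  branch qualifies as separable when it holds ≥ `min_module_size` genes
  and the gap between the merge absorbing it and its own top height is at
  least `gap_fraction` of the dendrogram's merge-height *span*
  (max − min). The span, not the maximum height, normalizes the gap
  because high soft-threshold powers compress all TOM dissimilarities
  toward 1 and leave the informative structure in a thin height band.
  Walking down from the root, the first separable branch containing no
  *divisive* split is accepted as a module. A divisive split is a merge
  of two module-sized branches that both cohere clearly below it —
  cohesion is each child's mean internal merge height, a summary that
  stray late-joining leaves cannot inflate — or, at any size, a split
  separated by more than half the height span. This keeps a module
  intact when a few stragglers join it near the top, while never
  accepting a branch that actually spans several well-separated
  clusters. Genes in branches too small to be modules stay grey
  (label 0).

Defaults: `min_module_size` 30, `gap_fraction` 0.005. The gap fraction
was fixed by the geometry of average-linkage TOM dendrograms: module
branches detach from the background with gaps of roughly 1–7% of the
height span, while merges inside a module or among background genes are
an order of magnitude tighter, so 0.5% separates the two regimes with
margin on either side.

Each module's eigengene is the first right-singular vector of its
z-scored (per gene, across samples) submatrix — the first principal
component — with unit norm over samples and sign aligned so it
correlates non-negatively with the module's mean standardized profile;
the explained-variance fraction is recorded. Modules are then merged
iteratively: average-linkage clustering of modules on 1 − cor(ME),
fusing clusters below `merge_cut_height` (default 0.25) and recomputing
eigengenes until a fixed point; the module count never increases. The
height 0.25 is taken as the operative merge parameter (an eigengene
correlation of 0.8 corresponds to height 0.2; where the two conventions
disagree the procedural height wins, and both are configurable).
Module membership kME is the genes × modules matrix of Pearson
correlations with the eigengenes. Colors follow the conventional
size-ordered palette (turquoise, blue, brown, ...), grey reserved for
unassigned genes, ties broken by smallest member symbol.

## Enrichment

Each (module, gene set) pair is tested with a one-sided ("greater")
Fisher's exact test on the 2×2 table conditioned on the analysis
universe — by default every gene in the final filtered matrix; grey
genes count toward the universe but belong to no module. One-sided
because the question is over-representation, not depletion. Raw p-values
drive module selection by default, matching the usual −log10(p) heatmap
presentation of such analyses; Benjamini–Hochberg q-values are computed
across all pairs and can be selected instead. Sets with no gene in the
universe are skipped with a warning. Genes carrying several phenotype
labels count once per set; sets are tested marginally.

## Prioritization

The degree of connectivity of gene g is
100 × (# within-module neighbours with weight ≥ threshold)/(module size − 1),
i.e. the percentage of possible intramodular partners, computed on the
TOM by default (the final network transform before clustering; raw
adjacency is available). The edge threshold defaults to the
within-module 90th percentile of weights — adaptive, because any fixed
absolute cutoff would be arbitrary across β values; an absolute
threshold can be configured. Candidates for a phenotype are the
22q13-region genes inside that phenotype's enriched modules with
kME > 0.7 (strict), ranked by degree descending, annotated with pLI
(consumed from a file, never fetched), and flagged top-tier when
pLI > 0.9. A phenotype without enriched modules yields an empty section
plus an explanatory note. Per-module edge lists (TSV and SIF) and a
node-attribute table (set labels, region flag) are exported for external
network visualization.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes,
at desk scale. On the log scale, gene g of module m is
x_g = λ_g e_m + sqrt(1 − λ_g²) ε_g with latent factor e_m and noise ε_g
standard normal over samples, so cor(x_g, e_m) = λ_g; background genes
are independent noise. Log values map to RPKM as v = 2^(x+c) − 1 clipped
at 0 (c = 3), so the pipeline's own log2(RPKM + 1) recovers x + c up to
the rare clip; the clip slightly distorts the low tail, accepted because
the filter needs genuinely low-RPKM genes. Near-zero genes are drawn
exponential with mean 0.05 RPKM.

Default benchmark: 5 modules × 60 genes, λ ~ U[0.6, 0.9], 100 background
genes, 20 near-zero genes, 120 samples, seed 20231026. ASD, ID, seizures
and language impairment are planted on modules 1–4 (half of each
module's genes labeled, plus 10 background labels each — overlap with
background keeps the sets imperfect, as real lists are); the region set
is planted on modules 1 and 5 (fraction 0.3) plus one extra hub gene in
module 1 with fixed loading 0.95 carrying the region label; hypotonia is
planted on 15 background genes only, so its no-enriched-module outcome
path is exercised by design. Near-zero genes each carry one random
phenotype label so per-set attrition through the expression filter is
visible in the log. Sample sizes and loadings are the benchmark's study
conditions and are not tuned per run.

Randomness: one numpy PCG64 stream (`default_rng(seed)`) consumed in a
fixed order (factors; per-module loadings, noise, hubs; background;
near-zero). Set planting uses a separate stream seeded `seed + 1` and
the synthetic pLI table `seed + 2`, so annotation and pLI choices cannot
perturb the expression stream; everything is deterministic given the
seed. The generator does not emulate BrainSpan's age/brain-structure
sample design, read counts, sample-level batch effects, or correlated
module factors (a correlation knob exists for testing merge behaviour).
Passing the benchmark therefore demonstrates correctness of the
machinery under the factor model — not performance on real brain data,
where module sizes, overlap and noise are less benign.

## Numerical choices and degenerate inputs

- Correlations via `numpy.corrcoef`; matching a two-pass scalar oracle
  to ≈1e−15 is asserted in tests. Zero-variance genes are an error named
  per gene (the expression filter upstream removes them in practice).
- TOM computed by matrix product with zeroed diagonal; symmetrized and
  clipped to [0, 1] against rounding; a zero denominator (two isolated
  genes) yields overlap 0.
- Eigengenes by SVD of the z-scored submatrix (population sd). The sign
  convention (non-negative correlation with the module mean profile)
  makes eigengenes reproducible across runs and platforms.
- Hierarchical clustering through `scipy.cluster.hierarchy.linkage`,
  which resolves ties deterministically; all module/label orderings are
  sorted before output, so full runs are byte-identical (the run log is
  timestamp-free and every artifact is checksummed into a manifest).
- Fisher's exact test via `scipy.stats.fisher_exact`; tests compare it
  to exact integer enumeration of the hypergeometric support. Under a
  permutation null its raw-p type-I rate sits slightly below nominal, as
  the discreteness of the exact test dictates.
- Config validation reports all violations at once and rejects unknown
  keys; every default standing in for a parameter the source protocol
  leaves unstated is tagged `paper-unstated` in the run log.

## Known limitations

- Dense matrices only (≤ 20k genes); no block-wise mode, no biweight
  midcorrelation, no Spearman adjacency.
- The dynamic branch cut is a deliberate simplification of the published
  Dynamic Hybrid algorithm (no PAM-like reassignment stage); with the
  cut method, cut parameters and minimum module size all being analyst
  choices, module boundaries on real data are sensitive to them. All
  such parameters are logged with every run.
- Intramodular degree depends on the edge-weight threshold rule; the
  adaptive 90th-percentile default makes ranks comparable across
  modules but is still a convention, documented as such.
- Functional-term annotation (e.g. DAVID) and gnomAD retrieval are out
  of scope: the pipeline exports per-module gene lists and consumes pLI
  from a file.
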