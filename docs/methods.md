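# Methods

This note documents the statistical procedures implemented in `ecotyper`,
the choices made where the design was genuinely open, what the synthetic
data generator does and does not emulate, and the package's known limits.

## Quality control and normalization

Droplet (UMI-count) cells are removed when they have fewer than 2,000 total
counts, fewer than 200 detected genes, or more than 10 % mitochondrial
counts (genes with the `MT-` prefix). The inequalities are strict in the
removal direction: a cell at exactly 2,000 UMIs, 200 genes or 10 % mito is
retained. Full-length TPM data bypasses the gate with a warning — such
cells arrive quality-filtered from their upstream quantification.
Normalization is per-cell scaling to 10,000 counts followed by ln(1+x) for
droplet data and log2(1+x) for TPM; a `normalized` flag makes double
normalization an error rather than a silent corruption.

## Two-run clustering and the contaminant purge

The first run is the standard graph pipeline: top-2000 highly variable
genes, PCA to 15 components, a shared-nearest-neighbor graph (k = 20) and
Leiden community detection at a caller-chosen resolution (Leiden is the
refinement of Louvain; the two agree on well-separated data, and Leiden's
determinism under a fixed seed is what the tests rely on). The second run
re-clusters each coarse cluster at resolution 50, producing mini-clusters
of a handful of cells.

No published criterion exists for which mini-clusters are contaminants, so
the rule here is a declared one: each coarse cluster is assigned its major
type by the majority of per-cell argmax marker-panel z-scores (robust even
when a single coarse cluster spans nearly all cells, where cluster-level
mean z-scores degenerate to ~0 for every panel), and a mini-cluster is
purged when the mean z-score of some *other* type's panel exceeds the own
type's mean by more than `contaminant_margin` (default 1.0 z-units). The
margin is needed because mini-clusters are tiny by construction and small
marker panels give per-cell scores with standard deviation near 0.5;
requiring a full z-unit of cross-panel dominance keeps false purging of
majority-type cells in the low percent range while genuine contaminants
(which sit several z-units toward their own panel) are always flagged.

## Tissue preference

For subset *i* in tissue *j*, the 2×2 table (a, b, c, d) described in the
README yields the *sample* odds ratio ad/bc (not the conditional-MLE
estimate some software reports) with a two-sided Fisher exact p defined as
the total probability of tables, at fixed margins, no more probable than
the observed one. When any cell of the table is zero, a Haldane correction
of 0.5 is added to all four cells *and the row is flagged* — non-degenerate
tables are never altered. Benjamini–Hochberg adjustment runs over all
(subset, tissue) pairs jointly. Labels use strict thresholds (OR > 1.5
enriched, OR < 0.5 depleted, both configurable). Ro/e
(observed / expected = a / (n_i n_j / N)) is emitted alongside because the
two statistics answer slightly different questions and heatmaps in this
field use either.

## Cross-platform MG/BMDM transfer

Microglia and macrophage canonical markers (P2RY12/TMEM119/CX3CR1/SALL1 vs
TGFBI/ITGA4/F13A1/CD163) are poorly detected on droplet platforms, while a
conserved core program separating the two lineages survives both platforms.
The pipeline therefore: (1) clusters full-length data at resolution 0.3 and
labels each cluster MG or BMDM by the higher mean z-scored marker-set
expression (exact ties are labeled ambiguous and excluded from training —
cheaper than training on noisy labels); (2) trains a random forest with 500
trees, √p features per split and out-of-bag error reporting, on the inner
join of the training datasets' gene spaces; (3) predicts droplet cells with
exact probability ties mapped to "ambiguous". Class weighting is not used.

Features are z-scored per gene *within each dataset* before training and
prediction. This is the one step where the package deviates from feeding
raw log-normalized expression to the forest: absolute log2-TPM and
ln-CP10K scales differ by several units, so tree thresholds learned on one
scale are meaningless on the other, whereas within-dataset z-scores put
both platforms on a shared relative scale. Classifier quality is inspected
via classical multidimensional scaling (cmdscale) of the forest proximity
matrix (1 − fraction of trees co-routing two cells to the same leaf).

Conserved DEGs are the per-tumor-type MG-vs-BMDM Wilcoxon markers
(logFC > 0.25, adjusted p < 0.01, strict) intersected across all source
types, direction-consistent; a gene significant in only one source is
excluded. The log-fold-change convention throughout the package is the
natural log of (mean expm1(normalized expression) + 1) ratios — the
dominant single-cell convention — and is stated here because upstream tools
disagree silently.

## Informative genes and cluster-number selection

Each dataset contributes a one-way ANOVA F per gene across its own
clusters, computed on log-normalized expression (variance stabilization;
counts would let library size masquerade as cluster signal). F values are
converted to within-dataset percentile ranks with the largest F mapping to
1.0; per gene the median rank across the datasets where it is detected is
taken. Genes from the ribosomal (RPL/RPS), cell-cycle and heat-shock
(HSP/DNAJ) families are excluded, a gene must be detected in strictly more
than half of the datasets, and the top 2000 by median rank form the
informative set. The rank direction is exposed (`rank_direction`) because
"ordered ascendingly" is ambiguous between the rank scale and the F scale;
the default keeps the most cluster-discriminating genes, which is the only
reading under which the selection has its intended effect. Datasets with a
single cluster have no F statistic and are skipped with a warning.

Meta-clustering restricts the PCA to the informative genes (all of them as
HVGs), scans Leiden resolutions 0.1–2.0 in steps of 0.1, computes the
Davies–Bouldin index on the PC coordinates (centroid-based, Euclidean) at
each resolution, and keeps the argmin. DBI is undefined for a single
cluster; such grid points are recorded as NaN and cannot be selected.
Solutions containing a cluster smaller than `min_cluster_size` (default 5
cells) are likewise excluded from the argmin: graph clustering at high
resolution occasionally splits off near-singleton shards whose ~zero
scatter *lowers* the DBI, so without the guard the index systematically
rewards these degenerate solutions.
Instead of anchor-based dataset integration (out of scope), cross-dataset
work uses per-dataset gene z-scoring before concatenation — adequate for
the desk-scale validation data, and a documented deviation from
integration-based pipelines for real multi-batch data.

The cross-tumor similarity tree z-scores genes across cells within each
dataset, averages per cluster, joins on genes present in all datasets, and
clusters the profiles with average linkage on 1 − Pearson distance (both
configurable; neither choice is canonical in the field). Trees serialize to
newick via scikit-bio.

## Markers, enrichment, set scores, marker pathways

Marker detection is one-vs-rest Wilcoxon rank-sum. When both groups have at
most 8 cells the p-value comes from exact enumeration of all group
assignments of the pooled (possibly tied) values; otherwise the
tie-corrected normal approximation with continuity correction is used. All
marker thresholds are strict inequalities.

Gene-set enrichment over a marker list is the one-sided hypergeometric
upper tail against a stated universe, BH-adjusted across sets; the
"enrichment score" used for ranking pathways is −log10(q) (the raw q is
also emitted, since a score and a q-value ranking can disagree only under
ties).

Per-cell pathway activity is a rank-based running-sum statistic: with
within-cell ranks r_j (average ties) and weights w_j = r_j^0.25, genes are
walked in decreasing expression order and the score is
(1/G) Σ_i [S_in(i)/(m·W/G) − S_all(i)/W], where S_in and S_all are the
cumulative weights of set genes and of all genes, m the set size, W the
total weight. Normalizing the in-set running mass by its expectation under
random gene placement (m·W/G), rather than by the realized in-set weight,
makes the null expectation of the score *exactly* zero — the classic
weighted-KS single-sample statistic is biased upward under the null because
rank weights correlate with walk position. The score depends only on
within-cell ranks, hence is invariant to any monotone per-cell transform.
The weight exponent (default 0.25) softens the top-rank dominance of the
unweighted statistic.

Differential pathway activity is a one-vs-rest moderated t: per-set pooled
variances are shrunk toward their across-set mean with 4 prior degrees of
freedom (an empirical-Bayes default of the same order as the shrinkage the
field's standard implementation applies; its exact prior is not printed
anywhere, so ours is declared). A plain Welch t is available behind
`method="welch"`. A cluster's *marker pathway* is determined by
intersecting its enriched and differential pathways, ranking by enrichment
score with ties broken toward the smaller set then lexicographically, and
taking the first pathway containing at least one of the cluster's top-10
markers by logFC; the pathway's reported marker gene is the contained top
marker with maximal logFC. When no candidate contains a top-10 marker the
result is an explicit no-call (real clusters do produce this outcome).

## scFes and immune-recruitment features

scFes derivation applies the per-platform threshold triples listed in the
README, with the strict full-length adjusted-p cut held in a config value
(`STRICT_P_FULL_LENGTH`, default 1e-20) because the printed form "10e-20"
is ambiguous between 1e-19 and 1e-20; the default takes the stricter
common reading. Combination rules: intersection over all datasets (common
types and subpopulations), at-least-three-quarters quorum (cytotoxic CD8),
and passing common-type thresholds in at least two tumor types (conserved
tumor features). Every signature stores its per-dataset marker sets and
thresholds, and `verify_signature` recomputes the derivation from the
source datasets — provenance is a checkable property, not metadata.

The exact construction of the positive/negative immune-recruitment
programs is a declared reconstruction: each tumor-expressed gene's Spearman
correlation with per-sample immune content (mean normalized PTPRC or a
planted immune fraction, configurable) across at least 8 samples, with
positive-IR = {ρ > 0.5, BH q < 0.1} and negative-IR its mirror; the two
lists are disjoint by construction. Correlation runs on tumor-cell
pseudobulk rather than raw bulk so the programs describe the tumor
compartment, not the immune admixture itself.

Signature scoring (used for both cells and bulk samples) is the mean of
per-gene z-scores over the set members present in the matrix; genes with
zero variance contribute 0, an all-degenerate set warns and returns zeros,
an empty overlap is an error, and the missing-gene fraction is reported on
the result. The score itself is nowhere defined in the upstream
literature; the mean z-score is the simplest scale-free choice, and a
rank-based alternative (`method="rank"`) is provided for sensitivity
analysis.

## Archetypes

Bulk samples are scored on the signature panel, the score columns z-scored
across samples, and k-means (20 restarts, fixed seed) run for each k in the
grid; the Davies–Bouldin minimum selects k (k-means on z-scored scores is a
declared choice — only the DBI selection itself is prescribed; a
hierarchical cut is a trivial swap). The grid must start at 2 (DBI is
undefined at k = 1) and near-duplicate centroids raise a warning.

Archetype gene features: for archetype A against each of the other k−1,
Welch t on log2 expression with p < 0.05 and log2FC > 1, top 3000 genes by
logFC per contrast, intersected across contrasts. Feature genes must be
detected (expression > 0) in at least 80 % of A's samples — read as 80 % of
*samples* in the bulk context — and when more than 20 remain, the 20 with
the lowest within-A coefficient of variation (linear scale) are kept. The
detection filter is applied in both branches (also when the intersection is
already ≤ 20 genes) so that the ≥ 80 % detection property holds for every
emitted feature unconditionally. An empty intersection yields an empty
feature with a warning; the archetype remains scoreable through the parent
panel. External projection scores samples on each archetype's gene feature
(mean z-score), assigns the argmax, and labels samples "unassigned" when
the top-two margin is below τ (default 0.1) — abstention is cheaper than a
coin-flip label.

Survival association is standard plumbing: Kaplan–Meier curves per group
with a multivariate log-rank p, and univariate Cox proportional-hazards
fits per score column (group labels are expanded to indicator covariates
when no scores are given). All-censored input is an error.

## The synthetic-data generator

`synthio` emulates the study conditions at desk scale. Droplet counts are
negative-binomial (gene-level means from log-normal baseline programs,
dispersion 0.5 — var = μ + 0.5 μ², the mid-range of droplet fits) with
per-cell log-normal library sizes (median 6,000 UMIs, σ = 0.25) and
Bernoulli dropout (base 10 %); full-length data are exponentiated Gaussian
programs (σ = 0.5 in log2) rescaled per cell to 10⁶ (TPM) and stored
pre-log, with 5 % dropout. Planted cell types up-regulate their canonical
markers plus a 15-gene auxiliary module at 8× (real cell types differ in
many genes, not four); marker baselines are floored at the median gene
baseline because a marker that is barely expressed anywhere is not a
marker. MG and BMDM inherit the myeloid program at half effect, carry
10-gene conserved core programs stable on both platforms, and their
canonical markers receive an extra 85 % dropout on droplet data — the
exact failure mode the random-forest transfer exists to beat.
Mitochondrial genes (`MT-` prefix) are pinned to 4 % of counts so the QC
rule is exercised literally; ribosomal, cell-cycle and heat-shock families
exist so exclusion lists act on real names. Type assignment is
deterministic ("exact" mode) by default for testability, with a multinomial
mode behind a switch. QC violations can be planted explicitly (low
library, few genes, or 30 % mito).

Pseudo-bulk cohorts mix the cell-type programs per archetype composition,
boost archetype-private genes, add Gaussian noise on the log2 scale, and
draw exponential survival with archetype-specific hazards under independent
exponential censoring. A dedicated helper plants positively and negatively
immune-correlated tumor programs against a uniform immune-content
covariate.

Deliberately **not** emulated: ambient RNA, doublets, batch effects beyond
per-dataset scale differences, compositional count dependencies beyond the
TPM rescale, gene–gene correlation structure within programs, and
non-proportional hazards. Passing tests therefore demonstrate that the
procedures recover *planted* structure under realistic noise — not that
they are robust to every artifact of real tissue data.

## Validation problem sizes

The test suite and the acceptance script validate on: 200–400 cells per
single-cell dataset over a ~500-gene universe (2–4 datasets per scenario),
160-sample bulk cohorts with four planted archetypes (40 per arm), 400
samples per arm for hazard-ratio recovery, and 10 random seeds for every
stochastic recovery claim (3 seeds for the scFes scenario, whose per-run
cost is dominated by four marker scans). These sizes keep each recovery
property measurable with comfortable margins while the whole validation
runs in minutes on one CPU.

## Known limitations

- The contaminant-purge rule, the IR construction, the signature scorer and
  the moderated-t prior are declared reconstructions where the upstream
  methods are under-specified; each is parameterized so alternatives can be
  tested.
- Cross-dataset work substitutes per-dataset z-scoring for anchor-based
  integration; real multi-batch data with strong batch structure needs a
  dedicated integration step upstream.
- The exact Wilcoxon path enumerates C(n1+n2, n1) assignments and is
  intentionally capped at group sizes of 8.
- Label transfer supports exactly two classes (MG vs BMDM); the forest
  itself would generalize, the surrounding contracts do not.
- The 9-feature panel composition is a default, not a law; it is
  overridable wherever it is consumed.
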