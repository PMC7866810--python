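# Methods

This note documents the statistical procedures implemented in `scbiodisc`,
the assumptions they rest on, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Normalization

Two size-factor estimators are provided, switchable by flag:

- `scale_to_median_total` (default): `factor_c = N_c / median(N)` with `N_c`
  the cell's total count over biological genes. Every normalized column then
  sums to the median raw library size. This is the simpler estimator and the
  default because it is defined for any matrix with positive cell totals.
- `median_of_ratios`: DESeq-style factors, `factor_c = median_g
  counts[g,c] / geomean_g` over genes with a positive geometric mean across
  cells, rescaled to geometric mean 1. It is robust to composition effects
  but undefined when no gene is expressed in every cell (sparse single-cell
  matrices often trip this; the error message points at the alternative).

Spike-in rows never contribute to factor estimation but are divided by the
same factors, so spike-in and biological genes stay on a common scale.
Normalization preserves the zero pattern exactly. Zero-safe shifts
(`+0.1`-style pseudocounts) are a display concern only and are never applied
before testing.

## Gene and cell filtering

The gene rule keeps genes with normalized expression ≥ `minexpr` in at least
`minnumber` cells; the cell rule removes cells whose *raw* biological total
is below `min_cell_counts` (default 1000 in the convenience mode). Cells are
filtered first, then genes are evaluated on the surviving cells; the order
matters only marginally but is fixed and documented here. The convenience
parameterization `median_expression_params` sets `minexpr` to the overall
median of the normalized matrix and `minnumber` to `ceil(0.10 · n_cells)`
("median expression in at least 10% of the cells"). Designed filtering is an
exact, case-sensitive intersection with a user gene list, reporting absent
genes rather than guessing at identifier aliases.

## Spike-in technical-noise filtering

The squared coefficient of variation of the normalized spike-ins is modelled
as `cv²(μ) = a1/μ + a0`: the `a1/μ` term is Poisson counting noise scaled by
library effects, `a0` the asymptotic technical CV² at high expression. The
fit is a Gamma-family GLM with identity link on the regressor `1/μ`
(falling back to ordinary least squares if the GLM fails to converge or
produces a non-positive curve), excluding spike-ins below the 20th
percentile of mean expression, where single-digit counts make CV² estimates
unstable. For each biological gene the statistic

    Var · (n − 1) / [ (a1 + δ)·μ + (a0 + δ)·μ² ]

is referred to χ²(n−1), with δ = `min_biol_disp` (default 0.25, i.e. a
minimum biological CV of 0.5) inflating the technical variance so that only
genes with substantial biological variability pass at `alpha` (default
0.01). Inflating the denominator makes the test conservative by design:
under pure technical noise the flagged fraction stays below alpha, which the
test suite verifies by simulation. All three constants are unstated in the
upstream literature for this pipeline and are exposed as arguments.

## Clustering and model selection

All clustering operates on `log2(x+1)` values — raw counts span four orders
of magnitude and untransformed Euclidean distances would be dominated by a
handful of high-expression genes.

**k-means + gap statistic.** For each k in the range, Lloyd iterations run
from 10 seeded restarts, keeping the run with the smallest within-cluster
dispersion W. Euclidean mode is classical Lloyd; Pearson mode assigns each
cell to the centroid with the smallest `1 − r` dissimilarity while
recomputing centroids as mean profiles (a medoid-style assignment in
correlation space; correlation is scale-free, which suits expression
profiles). The gap statistic compares `log W_k` against B reference datasets
drawn uniformly over the per-feature data range: `gap(k) = mean_b log
W_k(ref_b) − log W_k(data)`, `s_k = sd_b · sqrt(1 + 1/B)`. "The minimal
cluster number at the saturation level" is operationalized as the standard
first-crossing rule — the smallest k with `gap(k) ≥ gap(k+1) − s_{k+1}` —
because it is the testable textbook form of that idea. B defaults to 50;
a user-fixed k bypasses selection.

**Model-based clustering.** Counts are reduced to `n_pcs = min(20,
n_cells−1)` principal components, a Gaussian mixture is fitted by EM for
each k with diagonal and full covariance families, and the model maximizing
the BIC (in the `2·logL − k·log n` convention, so larger is better; the
sign-flip of scikit-learn's convention) is selected. On well-separated
Gaussian populations this recovers k exactly. Known limitation: on raw NB
count data the log transform leaves skewness that full-covariance mixtures
can absorb as spurious extra components, so BIC may overselect k by 1–2
there even when membership recovery (ARI) remains high; the k-means route is
the default for count data.

**Robustness.** Bootstrap Jaccard stability resamples cells with
replacement, reclusters with the same method and k, and matches each
original cluster (intersected with the sampled cells) to its best
new-cluster overlap `|A∩B|/|A∪B|`; values above 0.6 are conventionally
called stable. Bootstraps in which a cluster contributes no sampled cell are
skipped for that cluster; a cluster absent from every bootstrap reports 0
with a warning. Silhouette widths use the standard `(b−a)/max(a,b)` on any
cell-cell distance matrix; members of singleton clusters get width 0 by
convention. Ties in max-Jaccard matching break toward the lowest new-cluster
index.

**Distances.** `pearson` (1 − r), `euclidean` on log profiles, and
`euclidean_of_correlation` — Euclidean distance between rows of the
cell-cell correlation matrix — the two-step construction used for distance
heatmaps, whose rendering order comes from single-linkage clustering of
mean between-cluster distances.

## Outlier cells

Within each cluster of at least two cells, gene-level `log Var` is fitted as
a quadratic in `log mean` over genes with positive mean (pooling genes
borrows strength that per-gene variances at small cluster sizes lack). For
every gene and cell the upper-tail probability of the observed raw count is
computed under NB(mean = cluster mean, variance = fitted), with size
`r = μ²/(v−μ)`; where the fitted variance does not exceed the mean the
Poisson tail is used. Only over-expression counts as extreme — the upper
tail is the regime where a rare distinct cell type manifests. A gene with
p < `probthr` (default 1e-3) is an outlier gene; a cell with at least
`outminc` outlier genes is an outlier. The default `outminc` is 2; the
dataset-size-aware convention is `ceil(0.05 · n_genes)`, which controls the
false-flag rate when thousands of genes are tested per cell. Raw
(non-normalized) counts are used by default because the NB model describes
counting noise. Outlier cells are flagged, never re-assigned to new
clusters — a deliberate simplification that keeps the cluster labels stable
for downstream stages.

## Pseudotime

Cluster centers in the clustering PC space are joined by a Euclidean minimum
spanning tree; the backbone is the tree's weighted diameter (ties broken by
the lexicographically smallest endpoint pair). Each cell is projected
orthogonally onto its nearest backbone segment, with the projection clamped
to the segment so cells beyond a terminal center receive the terminal arc
length; pseudotime is the cumulative arc length to the projection point, and
the cell order sorts by pseudotime with index tie-breaks. Reversing the
backbone reflects pseudotime (`pt' = total − pt`), and the construction is
invariant to rigid rotations of the PC space. Within-cluster ordering by
projection (rather than cluster rank alone) was chosen because it uses the
geometry already computed and gives a strictly finer ordering. Expression
profiles along the ordering are reported as `log10(x+1)`; any smoothing is a
plotting concern and no statistic depends on it.

## Differential expression

**Resampled Wilcoxon two-class test.** Run on raw counts with spike-ins
excluded — rank statistics need the counting-noise scale, and normalization
would re-weight ties. Each resampling round Poisson-thins every cell to the
common minimum library depth (`rate = min_depth / depth_c`; cells already at
the minimum are left untouched, so with equal depths and one resample the
statistic is exactly the classical standardized rank-sum). Per gene, the
standardized Wilcoxon rank-sum statistic `(T − n₁(n+1)/2) /
sqrt(n₀n₁(n+1)/12)` is computed from within-gene ranks (the column-rank
kernel `rank_columns`, mean ranks on ties) and averaged over
`n_resamples = 20` rounds. The null distribution reuses the same resampled
rank matrices under `n_permutations = 100` label permutations. Q-values are
SAM-style: at the cut point `|d_i|`, FDR = (expected permuted call count) /
(observed call count), monotonized so a larger statistic never has a larger
q. The expectation (the original SAM "expected number of falsely called
genes") is used rather than the permutation median: at extreme cut points
the permuted call count lives on {0, 1} and its median collapses to 0 about
half the time, which would hand the top-ranked gene q = 0 under a complete
null — the expectation keeps the empirical FDR controlled, which the test
suite verifies over 50 null replicates. Fold changes are `log2` with
pseudocount 0.5 on both group means of the depth-equalized counts.

**Binomial marker test.** For a target cluster with total reads T, each
gene's count x is tested against Binomial(T, p₀), where p₀ is the gene's
smoothed share of the remaining cells' reads (`(rest + 0.5) / (rest_total +
0.5)`). The two-sided p-value is `2·min(upper tail, lower tail, 0.5)` —
a fixed, documented convention since tail conventions differ across
implementations — with BH q-values and fold change `(x/T)/p₀`. The test
conditions on read totals, so it is exact under multinomial read sharing but
anti-conservative when extra-multinomial (NB) cell-to-cell variation is
strong; it is a marker-ranking tool, and the resampled Wilcoxon test is the
inferential workhorse.

Volcano tables floor q at machine epsilon before `−log10` and flag genes
passing both the FDR and the linear fold-change threshold.

## Biomarker identification

**Decision trees.** The CART inducer searches all (gene, midpoint threshold)
pairs for the split minimizing weighted Gini impurity, recursing until a
node is pure, smaller than `minsplit` (default 20), or the best split's
impurity decrease relative to the root impurity falls below `cp` (default
0.01) — the conventional recursive-partitioning defaults. Thresholds are
midpoints of adjacent observed values; constant features can never be
chosen; ties break toward the earlier feature and smaller threshold. An
optional `c45` inducer swaps Gini for the entropy gain ratio with the same
stopping rules; it has no error-based pruning and is marked experimental.
Evaluation is stratified k-fold cross-validation (default 10) with pooled
confusion counts; sensitivity and specificity are reported for a declared
positive class, since the two swap meaning otherwise. Trees export as JSON
and Graphviz DOT.

**Network hubs.** The DEG list induces a subgraph of an offline interaction
edge list (deduplicated at load, max weight on conflicts, self-loops
dropped). Edge weights act only as a load-time confidence filter
(`min_weight`); centrality treats the network as unweighted, matching how
interaction-confidence scores are conventionally used. Hubs are ranked by
degree, then unnormalized Brandes betweenness (each unordered pair counted
once), then gene id; a normalization flag exists but the default reports raw
path counts since the subnetworks are small.

**Enrichment.** One-sided hypergeometric upper-tail p of the query/set
overlap within a declared universe, BH-corrected across sets. Query genes
outside the universe are dropped with a warning rather than silently
shrinking the universe.

## Synthetic data generator

Counts are negative binomial with mean `base_g · depth_c · FC_{g,cluster}`
and size r = 2 (variance μ + μ²/2, a typical single-cell overdispersion);
baseline means are log-normal (meanlog 1.5, sdlog 1.0, i.e. a median of
~4.5 counts with a long right tail), depth factors log-normal with sdlog
0.35 (a typical library-size spread). Each of the k clusters (default 3,
equal proportions, 300 cells) carries 10 disjoint marker genes at 8-fold
change. Spike-ins follow the technical-noise law `cv² = 3/μ + 0.1` exactly,
via NB draws whose size parameter matches the target variance. Trajectory
mode replaces discrete clusters by linear interpolation of cluster mean
profiles along a latent uniform position (labels become nearest-knot
assignments and the latent position is returned as ground truth). Injected
outlier cells have 8% of genes multiplied by 20 — above the 5%-of-genes
calling rule by a margin, because per-gene detection efficiency against a
heavy NB tail is below one for low-expression genes.

What it does **not** emulate: zero-inflation/dropout beyond what NB sampling
produces, batch effects, doublets, gene-gene correlation within clusters,
ambient RNA, or realistic gene-length/GC biases. Passing the recovery tests
therefore shows the algorithms are implemented correctly and behave as
designed under their own model assumptions — not that they are robust to
every artifact of real scRNA-seq data.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives per-stage seeds from a single global seed by hashing.
- `log W` in the gap statistic floors W at 1e-300; empty k-means clusters
  are reseeded on the farthest point.
- NB size parameters clamp `v − μ` away from 0; non-overdispersed fits fall
  back to Poisson tails.
- Zero-total cells, single-class tree inputs, single-cluster silhouette or
  pseudotime requests, empty filters and empty networks raise errors naming
  the offending entity rather than propagating NaNs.
- Problem sizes in the test and acceptance runs (hundreds of genes, tens to
  hundreds of cells, 20–50 simulation replicates) are chosen as the smallest
  sizes at which the statistical properties under test are comfortably
  resolved.
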