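# scbiodisc

Biomarker discovery in single-cell transcriptomics: a self-contained Python
library (with a thin CLI) that takes a genes × cells read-count matrix
through normalization and gene filtering, cellular clustering with
robustness assessment and outlier detection, pseudo-temporal ordering,
differential expression, and decision-tree / network / enrichment biomarker
identification. A seeded synthetic-data generator with known ground truth
makes every stage testable offline.

It is aimed at analysts who want the individual statistical steps of a
cell-sub-population study available as composable, inspectable functions
rather than a monolithic web pipeline.

## The methods at its core

- **Normalization** — per-cell size factors, either scaling each cell to the
  median library total (`factor_c = N_c / median(N)`) or DESeq-style median
  of ratios against a geometric-mean pseudo-reference.
- **Gene filtering** — three techniques: expression filtering (normalized
  expression ≥ *minexpr* in ≥ *minnumber* cells, with the convenience
  parameterization "overall median expression in ≥ 10% of cells"); designed
  filtering against a gene list of interest; and technical-noise filtering,
  fitting the ERCC spike-in noise law CV²(μ) = a₁/μ + a₀ by a Gamma GLM and
  keeping genes whose variance exceeds the inflated technical variance by a
  χ² test (statistic = Var·(n−1) / [(a₁+δ)μ + (a₀+δ)μ²], δ the minimum
  biological dispersion).
- **Clustering** — k-means (Euclidean or Pearson-dissimilarity mode) with
  the cluster number chosen by the gap statistic, Gap(k) = E*[log Wₖ] −
  log Wₖ, via the first-crossing rule Gap(k) ≥ Gap(k+1) − s_{k+1}; or
  Gaussian-mixture model-based clustering in PCA space with BIC selection.
  Robustness via bootstrap Jaccard stability and silhouette widths
  s(i) = (b−a)/max(a,b).
- **Outlier cells** — a per-cluster negative-binomial background model:
  log-variance fitted as a quadratic in log-mean across genes, cells flagged
  when ≥ *outminc* genes have NB upper-tail probability < *probthr*.
- **Pseudotime** — minimum spanning tree over cluster centers in PCA space;
  cells projected onto the tree's diameter path; pseudotime = cumulative arc
  length.
- **Differential expression** — a resampled Wilcoxon two-class test on raw
  counts (every cell Poisson-downsampled to the minimum library depth, the
  standardized rank-sum statistic averaged over resamples, q-values from a
  SAM-style permutation scheme), and a binomial marker test comparing each
  gene's share of a cluster's reads with its share elsewhere
  (X ~ Binomial(T, p₀), two-sided p = 2·min(upper, lower, ½), BH q-values).
- **Biomarkers** — CART decision trees (exhaustive Gini splits over midpoint
  thresholds, rpart-like cp stopping, stratified 10-fold CV), degree and
  Brandes betweenness hubs on a DEG-induced subnetwork of an offline
  interaction edge list, and hypergeometric gene-set enrichment from GMT
  files.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from scbiodisc import (SyntheticSpec, simulate, ClusteringParams,
                       cluster_kmeans_gap, jaccard_stability)

ds = simulate(SyntheticSpec(n_cells=300, seed=1))     # 3 planted clusters
bio = ds.table.biological()                           # drop spike-in rows
params = ClusteringParams(k_range=(1, 5), gap_refs=20, n_bootstrap=20, seed=2)
res = cluster_kmeans_gap(bio, params)
print(res.k, adjusted_rand_score(ds.labels, res.labels))
print(jaccard_stability(bio, res, params).jaccard.round(2).to_dict())
```

prints

```
3 1.0
{1: 1.0, 2: 1.0, 3: 1.0}
```

meaning the gap statistic selected three clusters, every cell was assigned
to its true population (adjusted Rand index 1.0), and each cluster was
rediscovered in essentially every bootstrap replicate (Jaccard stability 1.0,
far above the conventional 0.6 bar). The `examples/` directory has one short
script per capability — clustering, spike-in noise filtering, pseudotime,
differential expression, biomarkers, and the full pipeline — each printing
the numbers it computes and what they mean. The `scbiodisc` command exposes
the same stages from the shell (`scbiodisc run --config run.toml` for the
whole pipeline).

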