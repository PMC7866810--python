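"""Cell clustering, robustness assessment, outlier detection and embeddings.

Two clustering routes are provided: k-means with gap-statistic selection of
the cluster number (the minimal k at the saturation level of the gap curve,
operationalized as the Tibshirani first-crossing rule), and Gaussian-mixture
model-based clustering with BIC selection in PCA space. Cluster robustness is
assessed by bootstrap Jaccard stability and silhouette widths. Outlier cells
are detected against a per-cluster negative-binomial background model fitted
to the raw transcript counts.

All clustering operates on log2(x + 1)-transformed values; labels are 1-based
integers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

from .io import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringParams",
    "ClusteringResult",
    "StabilityReport",
    "OutlierParams",
    "OutlierReport",
    "Embedding",
    "distance_matrix",
    "cluster_kmeans_gap",
    "cluster_model_based",
    "jaccard_index",
    "jaccard_stability",
    "silhouette_widths",
    "detect_outliers",
    "compute_embedding",
    "order_clusters_hierarchically",
]


def log_transform(counts: np.ndarray) -> np.ndarray:
    """log2(x + 1), the working space for clustering and embeddings."""
    return np.log2(np.asarray(counts, dtype=float) + 1.0)


@dataclass
class ClusteringParams:
    method: str = "kmeans"  # or "model_based"
    k_range: tuple[int, int] = (1, 8)
    distance: str = "pearson"  # or "euclidean"
    n_bootstrap: int = 50
    gap_refs: int = 50
    seed: int = 0
    n_pcs: int = 20
    n_restarts: int = 10
    fixed_k: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid k_range {self.k_range}")
        if self.n_bootstrap < 1 or self.gap_refs < 1:
            raise ValueError("n_bootstrap and gap_refs must be >= 1")


@dataclass
class ClusteringResult:
    labels: np.ndarray  # 1..k per cell
    k: int
    centers: np.ndarray  # k x n_features mean profiles (log space)
    distance: str
    gap_curve: pd.DataFrame | None = None  # columns k, gap, sk
    bic_curve: pd.DataFrame | None = None  # columns k, bic
    params: ClusteringParams | None = None

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class StabilityReport:
    jaccard: pd.Series | None = None  # per-cluster mean bootstrap Jaccard
    silhouette: np.ndarray | None = None  # per-cell widths
    cluster_silhouette: pd.Series | None = None  # per-cluster mean width


@dataclass
class OutlierParams:
    probthr: float = 1e-3
    outminc: int = 2
    use_raw: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.probthr < 1.0:
            raise ValueError("probthr must lie in (0, 1)")
        if self.outminc < 1:
            raise ValueError("outminc must be >= 1")


@dataclass
class OutlierReport:
    outlier_gene_counts: pd.Series  # per cell
    min_p: pd.Series  # per cell, minimum gene-level tail p
    is_outlier: pd.Series  # per cell
    fits: dict[int, np.ndarray] = field(default_factory=dict)  # cluster -> poly coefficients

    def outlier_cells(self) -> list[str]:
        return list(self.is_outlier.index[self.is_outlier])


@dataclass
class Embedding:
    method: str
    coordinates: np.ndarray  # n_cells x 2
    seed: int
    explained_variance: np.ndarray | None = None
    perplexity: float | None = None


# ---------------------------------------------------------------------------
# distances


def _pearson_dissimilarity(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X."""
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant profile (zero variance) for rows {bad.tolist()}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def distance_matrix(table: ExpressionTable, metric: str = "pearson") -> np.ndarray:
    """Cell-cell distance matrix in log2(x + 1) space.

    Metrics: ``pearson`` (1 - r over genes), ``euclidean`` (over log
    expression profiles) and ``euclidean_of_correlation`` (Euclidean distance
    between rows of the cell-cell Pearson correlation matrix, the two-step
    construction used for distance heatmaps).
    """
    if table.n_cells < 2:
        raise ValueError("need at least 2 cells")
    X = log_transform(table.counts).T  # cells x genes
    if metric == "pearson":
        try:
            return _pearson_dissimilarity(X)
        except ValueError as exc:
            raise ValueError(f"pearson distance undefined: {exc}") from exc
    if metric == "euclidean":
        return scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(X, metric="euclidean")
        )
    if metric == "euclidean_of_correlation":
        r = np.corrcoef(X)
        return scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(r, metric="euclidean")
        )
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# k-means + gap statistic


def _kmeans_once(
    X: np.ndarray, k: int, distance: str, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run; returns (labels 0-based, centers, within-dispersion W).

    Euclidean mode is classical Lloyd. Pearson mode assigns each cell to the
    centroid with smallest 1 - r dissimilarity while recomputing centroids as
    mean profiles (a medoid-style assignment in correlation space).
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False), :].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = _point_center_dissim(X, centers, distance)
        new_labels = d.argmin(axis=1)
        # keep clusters non-empty: reseed an empty cluster on the farthest point
        for j in range(k):
            if not (new_labels == j).any():
                far = d[np.arange(n), new_labels].argmax()
                new_labels[far] = j
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    d = _point_center_dissim(X, centers, distance)
    W = float(d[np.arange(n), labels].sum())
    return labels, centers, W


def _point_center_dissim(X: np.ndarray, centers: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return scipy.spatial.distance.cdist(X, centers, metric="sqeuclidean")
    if distance == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        Cc = centers - centers.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(Xc, axis=1)
        cn = np.linalg.norm(Cc, axis=1)
        xn = np.where(xn == 0, 1.0, xn)
        cn = np.where(cn == 0, 1.0, cn)
        r = (Xc / xn[:, None]) @ (Cc / cn[:, None]).T
        return 1.0 - r
    raise ValueError(f"unknown distance {distance!r}")


def _kmeans_best(
    X: np.ndarray, k: int, distance: str, rng: np.random.Generator, n_restarts: int
) -> tuple[np.ndarray, np.ndarray, float]:
    if k == 1:
        center = X.mean(axis=0, keepdims=True)
        W = float(_point_center_dissim(X, center, distance)[:, 0].sum())
        return np.zeros(X.shape[0], dtype=int), center, W
    best = None
    for _ in range(n_restarts):
        run = _kmeans_once(X, k, distance, rng)
        if best is None or run[2] < best[2]:
            best = run
    return best  # type: ignore[return-value]


def cluster_kmeans_gap(table: ExpressionTable, params: ClusteringParams) -> ClusteringResult:
    """K-means clustering with gap-statistic selection of k.

    For every k in ``k_range``, k-means is run (best of ``n_restarts`` by
    within-cluster dispersion). The gap statistic compares log W_k of the data
    against reference datasets drawn uniformly over the per-feature range;
    ``gap(k) = mean_b log W_k(ref_b) - log W_k(data)`` and
    ``s_k = sd_b * sqrt(1 + 1/B)``. The chosen k is the smallest k with
    ``gap(k) >= gap(k+1) - s_{k+1}`` (first crossing); ``fixed_k`` bypasses
    selection.
    """
    if params.method != "kmeans":
        raise ValueError("params.method must be 'kmeans'")
    X = log_transform(table.counts).T
    n = X.shape[0]
    kmin, kmax = params.k_range
    if params.fixed_k is not None:
        kmin = kmax = params.fixed_k
    if kmax >= n:
        raise ValueError(f"k_range max {kmax} must be < n_cells {n}")
    rng = np.random.default_rng(params.seed)

    ks = list(range(kmin, kmax + 1))
    runs = {k: _kmeans_best(X, k, params.distance, rng, params.n_restarts) for k in ks}

    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps, sks = [], []
    for k in ks:
        logW_refs = np.empty(params.gap_refs)
        for b in range(params.gap_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            _, _, Wref = _kmeans_best(ref, k, params.distance, rng, max(3, params.n_restarts // 3))
            logW_refs[b] = np.log(max(Wref, 1e-300))
        gaps.append(float(logW_refs.mean() - np.log(max(runs[k][2], 1e-300))))
        sks.append(float(logW_refs.std(ddof=1) * np.sqrt(1.0 + 1.0 / params.gap_refs)))
    gap_curve = pd.DataFrame({"k": ks, "gap": gaps, "sk": sks})

    if params.fixed_k is not None:
        chosen = params.fixed_k
    else:
        chosen = ks[-1]
        for i in range(len(ks) - 1):
            if gaps[i] >= gaps[i + 1] - sks[i + 1]:
                chosen = ks[i]
                break
    labels, centers, _ = runs[chosen]
    return ClusteringResult(
        labels=labels + 1,
        k=chosen,
        centers=centers,
        distance=params.distance,
        gap_curve=gap_curve,
        params=params,
    )


# ---------------------------------------------------------------------------
# model-based clustering


def _pca_space(X: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    n_pcs = max(1, min(n_pcs, X.shape[0] - 1, X.shape[1]))
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(X)


def cluster_model_based(table: ExpressionTable, params: ClusteringParams) -> ClusteringResult:
    """Gaussian-mixture clustering with BIC model selection.

    Counts are log2(x + 1)-transformed and reduced to ``n_pcs`` principal
    components; for every k in ``k_range`` a mixture is fitted by EM with
    diagonal and full covariance families, and the model maximizing the BIC
    (2 log L - params * log n convention, so larger is better) is chosen.
    """
    if params.method != "model_based":
        raise ValueError("params.method must be 'model_based'")
    X = log_transform(table.counts).T
    n = X.shape[0]
    kmin, kmax = params.k_range
    if params.fixed_k is not None:
        kmin = kmax = params.fixed_k
    if kmax > n:
        raise ValueError(f"k_range max {kmax} exceeds n_cells {n}")
    Z = _pca_space(X, params.n_pcs, params.seed)

    best = None
    rows = []
    for k in range(kmin, kmax + 1):
        best_k = None
        for cov in ("diag", "full"):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                random_state=params.seed,
                n_init=3,
                reg_covar=1e-4,
                max_iter=500,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(Z)
            if not gm.converged_:
                raise RuntimeError(f"EM did not converge for k={k}, family={cov}")
            bic = -gm.bic(Z)  # flip sklearn's lower-is-better convention
            if best_k is None or bic > best_k[0]:
                best_k = (bic, gm, cov)
        rows.append({"k": k, "bic": best_k[0], "family": best_k[2]})
        if best is None or best_k[0] > best[0]:
            best = (*best_k, k)
    bic_curve = pd.DataFrame(rows)
    _, gm, _, chosen = best
    labels0 = gm.predict(Z)
    # relabel to consecutive 1..k' in case a component is empty
    uniq = np.unique(labels0)
    remap = {u: i for i, u in enumerate(uniq)}
    labels0 = np.array([remap[v] for v in labels0])
    k_eff = len(uniq)
    centers = np.vstack([X[labels0 == j].mean(axis=0) for j in range(k_eff)])
    return ClusteringResult(
        labels=labels0 + 1,
        k=k_eff,
        centers=centers,
        distance="euclidean",
        bic_curve=bic_curve,
        params=params,
    )


# ---------------------------------------------------------------------------
# robustness


def _recluster(table: ExpressionTable, params: ClusteringParams, k: int, seed: int) -> np.ndarray:
    p = replace(params, fixed_k=k, seed=seed)
    if params.method == "model_based":
        return cluster_model_based(table, p).labels
    return cluster_kmeans_gap(table, p).labels


def jaccard_index(a: set, b: set) -> float:
    """|A n B| / |A u B|; 1.0 for two empty sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def jaccard_stability(
    table: ExpressionTable, result: ClusteringResult, params: ClusteringParams
) -> StabilityReport:
    """Bootstrap Jaccard stability of the detected clusters.

    Each bootstrap resamples cells with replacement and reclusters with the
    same method and k; each original cluster, intersected with the sampled
    cell set, is matched to the best-overlapping new cluster by the Jaccard
    index |A n B| / |A u B| on original cell indices. Values near 1 mean the
    cluster is consistently rediscovered; the conventional stability bar is
    0.6.
    """
    rng = np.random.default_rng(params.seed + 7)
    k = result.k
    orig = {c: set(np.flatnonzero(result.labels == c)) for c in range(1, k + 1)}
    sums = {c: 0.0 for c in orig}
    hits = {c: 0 for c in orig}
    for b in range(params.n_bootstrap):
        idx = rng.choice(table.n_cells, size=table.n_cells, replace=True)
        sampled = set(idx.tolist())
        # resampled cells get fresh ids: the same cell may be drawn twice
        sub = ExpressionTable(
            table.gene_ids,
            [f"bs{i}" for i in range(table.n_cells)],
            table.counts[:, idx],
            table.is_spikein,
        )
        try:
            new_labels = _recluster(sub, params, k, int(rng.integers(2**31)))
        except ValueError:
            continue
        new_sets = [
            {int(idx[i]) for i in np.flatnonzero(new_labels == c)}
            for c in np.unique(new_labels)
        ]
        for c, A in orig.items():
            A_s = A & sampled
            if not A_s:
                continue
            best = max((jaccard_index(A_s, B) for B in new_sets if B), default=0.0)
            sums[c] += best
            hits[c] += 1
    jac = {}
    for c in orig:
        if hits[c] == 0:
            logger.warning("cluster %d vanished from every bootstrap sample", c)
            jac[c] = 0.0
        else:
            jac[c] = sums[c] / hits[c]
    return StabilityReport(jaccard=pd.Series(jac, name="jaccard"))


def silhouette_widths(dist: np.ndarray, labels: np.ndarray) -> StabilityReport:
    """Per-cell silhouette widths s(i) = (b - a) / max(a, b) on a distance matrix.

    ``a`` is the mean distance to the cell's own cluster, ``b`` the mean
    distance to the nearest other cluster. Members of singleton clusters get
    width 0 by convention.
    """
    labels = np.asarray(labels)
    dist = np.asarray(dist, dtype=float)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = labels.size
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        if not same.any():
            s[i] = 0.0  # singleton convention
            continue
        a = dist[i, same].mean()
        b = min(dist[i, labels == c].mean() for c in clusters if c != own)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    per_cluster = pd.Series(
        {int(c): float(s[labels == c].mean()) for c in clusters}, name="silhouette"
    )
    return StabilityReport(silhouette=s, cluster_silhouette=per_cluster)


# ---------------------------------------------------------------------------
# outlier detection


def nb_upper_tail(x: float, mean: float, variance: float) -> float:
    """P(X >= x) for a negative binomial with the given mean and variance.

    The NB size parameter is r = mean^2 / (variance - mean); when the fitted
    variance does not exceed the mean the Poisson tail is used instead.
    """
    if mean <= 0:
        return 1.0
    if variance > mean:
        r = mean**2 / (variance - mean)
        p = r / (r + mean)
        return float(scipy.stats.nbinom.sf(x - 1, r, p))
    return float(scipy.stats.poisson.sf(x - 1, mean))


def detect_outliers(
    table: ExpressionTable, result: ClusteringResult, oparams: OutlierParams | None = None
) -> OutlierReport:
    """Flag outlier cells against a per-cluster negative-binomial background.

    Within each cluster of >= 2 cells, the gene-level mean-variance relation
    is modelled as log v = c0 + c1 log m + c2 (log m)^2 over genes with
    positive mean; for each gene and cell the NB upper-tail probability of the
    observed raw count is computed under the cluster mean and fitted variance.
    A gene is an outlier gene in a cell if that probability falls below
    ``probthr``; a cell is an outlier if it accumulates at least ``outminc``
    outlier genes. The default ``outminc`` is 2; a dataset-size-aware
    alternative is 5% of the number of filtered genes.
    """
    oparams = oparams or OutlierParams()
    mat = table.counts if oparams.use_raw else log_transform(table.counts)
    counts = pd.Series(0, index=table.cell_ids, dtype=int, name="outlier_genes")
    minp = pd.Series(1.0, index=table.cell_ids, name="min_p")
    fits: dict[int, np.ndarray] = {}
    for c in range(1, result.k + 1):
        members = np.flatnonzero(result.labels == c)
        if members.size < 2:
            logger.warning("cluster %d has < 2 cells; skipped in outlier model", c)
            continue
        sub = mat[:, members]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = (m > 0) & (v > 0)
        if ok.sum() < 3:
            logger.warning("cluster %d has too few variable genes; skipped", c)
            continue
        logm, logv = np.log(m[ok]), np.log(v[ok])
        coef = np.polyfit(logm, logv, deg=2)
        fits[c] = coef
        pos = np.flatnonzero(m > 0)
        mu = m[pos][:, None]
        vhat = np.exp(np.polyval(coef, np.log(m[pos])))[:, None]
        x = mat[np.ix_(pos, members)]
        # NB tail where the fitted variance is over-dispersed, Poisson otherwise
        overdisp = vhat > mu
        r = np.where(overdisp, mu**2 / np.maximum(vhat - mu, 1e-12), 1.0)
        p_nb = scipy.stats.nbinom.sf(x - 1, r, r / (r + mu))
        p_pois = scipy.stats.poisson.sf(x - 1, mu)
        p = np.where(overdisp, p_nb, p_pois)
        # upper-tail model: only over-expression counts as extreme
        p = np.where(x > mu, p, 1.0)
        cells = [table.cell_ids[j] for j in members]
        minp[cells] = np.minimum(minp[cells].to_numpy(), p.min(axis=0))
        counts[cells] = counts[cells].to_numpy() + (p < oparams.probthr).sum(axis=0)
    flags = counts >= oparams.outminc
    flags.name = "is_outlier"
    return OutlierReport(outlier_gene_counts=counts, min_p=minp, is_outlier=flags, fits=fits)


# ---------------------------------------------------------------------------
# embeddings and heatmap ordering


def compute_embedding(
    table: ExpressionTable, method: str = "pca", seed: int = 0, perplexity: float = 30.0
) -> Embedding:
    """2-D embedding of cells for cluster visualization (PCA or tSNE)."""
    if table.n_cells < 3:
        raise ValueError("need at least 3 cells")
    X = log_transform(table.counts).T
    if method == "pca":
        pca = PCA(n_components=2, random_state=seed)
        coords = pca.fit_transform(X - X.mean(axis=0))
        return Embedding("pca", coords, seed, explained_variance=pca.explained_variance_)
    if method == "tsne":
        if perplexity >= (table.n_cells - 1) / 3:
            raise ValueError(
                f"perplexity {perplexity} too large for {table.n_cells} cells"
            )
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)
        return Embedding("tsne", np.asarray(coords, dtype=float), seed, perplexity=perplexity)
    raise ValueError(f"unknown embedding method {method!r}")


def order_clusters_hierarchically(dist: np.ndarray, labels: np.ndarray) -> list[int]:
    """Leaf order of a single-linkage dendrogram over cluster-center distances.

    Cluster-to-cluster distance is the mean cell-cell distance between the
    clusters; the returned order (1-based cluster ids) is the heatmap
    rendering order.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    k = clusters.size
    cd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            block = dist[np.ix_(labels == clusters[i], labels == clusters[j])]
            cd[i, j] = cd[j, i] = block.mean()
    Z = scipy.cluster.hierarchy.linkage(scipy.spatial.distance.squareform(cd), method="single")
    order = scipy.cluster.hierarchy.leaves_list(Z)
    return [int(clusters[i]) for i in order]
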