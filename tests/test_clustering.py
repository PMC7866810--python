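import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from conftest import blob_table
from scbiodisc.clustering import (
    ClusteringParams,
    OutlierParams,
    cluster_kmeans_gap,
    cluster_model_based,
    compute_embedding,
    detect_outliers,
    distance_matrix,
    jaccard_index,
    jaccard_stability,
    nb_upper_tail,
    order_clusters_hierarchically,
    silhouette_widths,
)
from scbiodisc.io import ExpressionTable
from scbiodisc.synthetic import SyntheticSpec, simulate


def table_from_cells(X):
    """cells x features -> ExpressionTable (genes x cells)."""
    X = np.asarray(X, dtype=float)
    return ExpressionTable(
        [f"G{i}" for i in range(X.shape[1])],
        [f"C{j}" for j in range(X.shape[0])],
        X.T,
    )


class TestDistanceMatrix:
    def test_identical_cells_distance_zero(self):
        t = table_from_cells([[1, 5, 2, 8], [1, 5, 2, 8], [3, 1, 9, 2]])
        for metric in ("pearson", "euclidean", "euclidean_of_correlation"):
            d = distance_matrix(t, metric)
            assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
            assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_anticorrelated_profiles_pearson_two(self):
        # log2(x+1) of these profiles is exactly anti-correlated
        a = np.array([1, 3, 7], dtype=float)
        b = 2.0 ** (np.log2(a[::-1] + 1)) - 1
        t = table_from_cells([a, b, [0, 1, 2]])
        d = distance_matrix(t, "pearson")
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_euclidean_of_correlation_matches_two_step_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 50, size=(4, 6))
        t = table_from_cells(X)
        d = distance_matrix(t, "euclidean_of_correlation")
        L = np.log2(X + 1)
        r = np.corrcoef(L)
        expect = np.array([[np.linalg.norm(r[i] - r[j]) for j in range(4)] for i in range(4)])
        np.testing.assert_allclose(d, expect, atol=1e-12)

    def test_constant_cell_pearson_error(self):
        t = table_from_cells([[1, 1, 1], [2, 5, 9]])
        with pytest.raises(ValueError, match="constant"):
            distance_matrix(t, "pearson")

    def test_permuting_cells_permutes_distances(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 10, size=(8, 5))
        perm = rng.permutation(8)
        d = distance_matrix(table_from_cells(X), "euclidean")
        dp = distance_matrix(table_from_cells(X[perm]), "euclidean")
        np.testing.assert_allclose(dp, d[np.ix_(perm, perm)], atol=1e-12)


class TestKmeansGap:
    def test_three_separated_blobs_recovered(self):
        centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0]], dtype=float)
        t = blob_table(centers, n_per=20, sd=1.0, seed=1)
        params = ClusteringParams(k_range=(1, 5), distance="euclidean",
                                  gap_refs=20, seed=2)
        res = cluster_kmeans_gap(t, params)
        truth = np.repeat([0, 1, 2], 20)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_single_blob_selects_one(self):
        t = blob_table(np.array([[5.0, 5.0, 5.0]]), n_per=40, sd=1.0, seed=4)
        params = ClusteringParams(k_range=(1, 4), distance="euclidean",
                                  gap_refs=30, seed=5)
        assert cluster_kmeans_gap(t, params).k == 1

    def test_fixed_k_bypasses_selection(self):
        t = blob_table(np.array([[0.0, 0.0], [10.0, 0.0]]), n_per=15, sd=0.5, seed=6)
        params = ClusteringParams(k_range=(1, 5), fixed_k=4, distance="euclidean",
                                  gap_refs=5, seed=7)
        assert cluster_kmeans_gap(t, params).k == 4

    def test_k_range_exceeding_cells_is_error(self):
        t = blob_table(np.array([[0.0, 0.0]]), n_per=5, sd=0.5, seed=8)
        with pytest.raises(ValueError, match="k_range"):
            cluster_kmeans_gap(t, ClusteringParams(k_range=(1, 6), gap_refs=2, seed=0))

    def test_uniform_blob_tends_to_k_one(self):
        """Gap selection on a single uniform cloud picks k=1 in >= 90% of reps."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            X = rng.uniform(0, 10, size=(40, 3))
            t = table_from_cells(X)
            params = ClusteringParams(k_range=(1, 3), distance="euclidean",
                                      gap_refs=100, seed=rep, n_restarts=5)
            if cluster_kmeans_gap(t, params).k == 1:
                hits += 1
        assert hits >= 0.9 * reps

    def test_pearson_mode_separates_correlation_structure(self):
        rng = np.random.default_rng(9)
        base1 = rng.uniform(1, 10, size=30)
        base2 = base1[::-1].copy()
        cells = [base1 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.2, 30) for _ in range(15)]
        cells += [base2 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.2, 30) for _ in range(15)]
        t = table_from_cells(np.maximum(np.array(cells), 0))
        params = ClusteringParams(k_range=(2, 2), fixed_k=2, distance="pearson",
                                  gap_refs=2, seed=10)
        res = cluster_kmeans_gap(t, params)
        truth = np.repeat([0, 1], 15)
        assert adjusted_rand_score(truth, res.labels) == 1.0


class TestModelBased:
    def test_two_gaussians_selected_and_recovered(self):
        centers = np.array([[0.0] * 4, [30.0] * 4])
        t = blob_table(centers, n_per=25, sd=1.0, seed=11)
        params = ClusteringParams(method="model_based", k_range=(1, 4), seed=12, n_pcs=3)
        res = cluster_model_based(t, params)
        truth = np.repeat([0, 1], 25)
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_single_gaussian_selects_one(self):
        t = blob_table(np.array([[10.0] * 4]), n_per=50, sd=1.0, seed=13)
        params = ClusteringParams(method="model_based", k_range=(1, 3), seed=14, n_pcs=3)
        assert cluster_model_based(t, params).k == 1

    def test_fixed_seed_reproduces_labels(self):
        t = blob_table(np.array([[0.0] * 3, [8.0] * 3]), n_per=20, sd=1.5, seed=15)
        params = ClusteringParams(method="model_based", k_range=(1, 3), seed=16, n_pcs=2)
        a = cluster_model_based(t, params)
        b = cluster_model_based(t, params)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestStability:
    def test_jaccard_index_basics(self):
        assert jaccard_index({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard_index({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_separable_blobs_exceed_stability_bar(self):
        centers = np.array([[0, 0, 0], [25, 0, 0], [0, 25, 0]], dtype=float)
        t = blob_table(centers, n_per=20, sd=1.0, seed=17)
        params = ClusteringParams(k_range=(3, 3), fixed_k=3, distance="euclidean",
                                  n_bootstrap=20, gap_refs=2, seed=18)
        res = cluster_kmeans_gap(t, params)
        rep = jaccard_stability(t, res, params)
        assert (rep.jaccard > 0.6).all()
        assert ((rep.jaccard >= 0) & (rep.jaccard <= 1)).all()

    def test_silhouette_matches_brute_force_oracle(self):
        rng = np.random.default_rng(19)
        X = rng.uniform(0, 10, size=(10, 4))
        d = distance_matrix(table_from_cells(X), "euclidean")
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3])
        rep = silhouette_widths(d, labels)

        expect = np.zeros(10)
        for i in range(10):
            a = np.mean([d[i, j] for j in range(10) if labels[j] == labels[i] and j != i])
            b = min(
                np.mean([d[i, j] for j in range(10) if labels[j] == c])
                for c in {1, 2, 3} - {labels[i]}
            )
            expect[i] = (b - a) / max(a, b)
        np.testing.assert_allclose(rep.silhouette, expect, atol=1e-12)

    def test_tight_clusters_high_mean_width(self):
        centers = np.array([[0.0, 0.0], [100.0, 0.0]])
        t = blob_table(centers, n_per=10, sd=0.5, seed=20)
        d = distance_matrix(t, "euclidean")
        rep = silhouette_widths(d, np.repeat([1, 2], 10))
        assert rep.silhouette.mean() > 0.9

    def test_singleton_gets_zero(self):
        d = distance_matrix(table_from_cells(np.random.default_rng(21).uniform(0, 5, (4, 3))),
                            "euclidean")
        rep = silhouette_widths(d, np.array([1, 1, 1, 2]))
        assert rep.silhouette[3] == 0.0

    def test_single_cluster_error(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            silhouette_widths(d, np.array([1, 1, 1]))

    def test_silhouette_bounds_on_fuzzed_inputs(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            n = rng.integers(4, 15)
            X = rng.uniform(0, 10, size=(n, 3))
            d = distance_matrix(table_from_cells(X), "euclidean")
            labels = rng.integers(1, 4, size=n)
            if len(np.unique(labels)) < 2:
                continue
            rep = silhouette_widths(d, labels)
            assert (rep.silhouette >= -1 - 1e-12).all()
            assert (rep.silhouette <= 1 + 1e-12).all()


class TestOutliers:
    def test_nb_tail_matches_direct_summation(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            mean = rng.uniform(0.5, 50)
            var = mean * rng.uniform(1.1, 5.0)
            x = int(rng.integers(0, 200))
            r = mean**2 / (var - mean)
            p = r / (r + mean)
            direct = 1.0 - sum(scipy.stats.nbinom.pmf(k, r, p) for k in range(x))
            assert nb_upper_tail(x, mean, var) == pytest.approx(direct, abs=1e-10)

    def test_injected_cell_is_the_only_outlier(self):
        """Homogeneous NB cluster plus one cell with 20x counts in 6 genes."""
        rng = np.random.default_rng(24)
        n_genes, n_cells = 100, 40
        mu = rng.uniform(5, 50, size=n_genes)
        r = 2.0
        counts = rng.poisson(rng.gamma(r, np.tile(mu[:, None], (1, n_cells)) / r)).astype(float)
        hit = rng.choice(n_genes, size=6, replace=False)
        counts[hit, 7] = np.maximum(counts[hit, 7], 1) * 20
        t = ExpressionTable([f"G{i}" for i in range(n_genes)],
                            [f"C{j}" for j in range(n_cells)], counts)
        labels = np.ones(n_cells, dtype=int)
        from scbiodisc.clustering import ClusteringResult

        res = ClusteringResult(labels=labels, k=1, centers=counts.mean(axis=1)[None, :],
                               distance="euclidean")
        rep = detect_outliers(t, res, OutlierParams(probthr=1e-3, outminc=2))
        assert rep.outlier_cells() == ["C7"]

    def test_default_outminc_is_two(self):
        assert OutlierParams().outminc == 2

    def test_flag_iff_count_reaches_outminc(self, three_cluster_dataset):
        ds = three_cluster_dataset
        bio = ds.table.biological()
        params = ClusteringParams(k_range=(3, 3), fixed_k=3, gap_refs=2, seed=0)
        res = cluster_kmeans_gap(bio, params)
        rep = detect_outliers(bio, res, OutlierParams(outminc=3))
        np.testing.assert_array_equal(
            rep.is_outlier.to_numpy(), (rep.outlier_gene_counts >= 3).to_numpy()
        )
        assert (rep.outlier_gene_counts <= bio.n_genes).all()


class TestEmbedding:
    def test_pca_preserves_planar_distances(self):
        rng = np.random.default_rng(25)
        X2 = rng.uniform(0, 10, size=(12, 2))
        t = table_from_cells(X2)
        emb = compute_embedding(t, "pca", seed=0)
        L = np.log2(X2 + 1)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb.coordinates), pdist(L), atol=1e-8)

    def test_pca_variance_ordering(self, three_cluster_dataset):
        emb = compute_embedding(three_cluster_dataset.table.biological(), "pca", seed=0)
        assert emb.explained_variance[0] >= emb.explained_variance[1]

    def test_tsne_deterministic_for_seed(self):
        rng = np.random.default_rng(26)
        t = table_from_cells(rng.uniform(0, 20, size=(30, 10)))
        a = compute_embedding(t, "tsne", seed=3, perplexity=5.0)
        b = compute_embedding(t, "tsne", seed=3, perplexity=5.0)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_perplexity_bound(self):
        t = table_from_cells(np.random.default_rng(27).uniform(0, 5, (10, 4)))
        with pytest.raises(ValueError, match="perplexity"):
            compute_embedding(t, "tsne", seed=0, perplexity=5.0)


class TestHeatmapOrder:
    def test_two_clusters_identity_or_reverse(self):
        d = distance_matrix(
            table_from_cells(np.random.default_rng(28).uniform(0, 10, (6, 3))), "euclidean"
        )
        order = order_clusters_hierarchically(d, np.array([1, 1, 1, 2, 2, 2]))
        assert order in ([1, 2], [2, 1])

    def test_collinear_middle_never_terminal(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        t = blob_table(centers, n_per=5, sd=0.1, seed=29)
        d = distance_matrix(t, "euclidean")
        labels = np.repeat([1, 2, 3], 5)
        order = order_clusters_hierarchically(d, labels)
        assert order[1] == 2  # the middle cluster sits between the ends

    def test_order_is_permutation(self, three_cluster_dataset):
        ds = three_cluster_dataset
        d = distance_matrix(ds.table.biological(), "euclidean")
        order = order_clusters_hierarchically(d, ds.labels)
        assert sorted(order) == [1, 2, 3]


class TestPipelineRecovery:
    def test_marker_structured_counts_cluster_perfectly(self, three_cluster_dataset):
        ds = three_cluster_dataset
        params = ClusteringParams(k_range=(1, 5), gap_refs=10, seed=1)
        res = cluster_kmeans_gap(ds.table.biological(), params)
        assert res.k == 3
        assert adjusted_rand_score(ds.labels, res.labels) >= 0.95
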