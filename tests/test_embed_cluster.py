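import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from scvuln.embed_cluster import (
    build_knn_jaccard,
    cluster_similarity,
    cross_tabulate,
    embed_2d,
    jackstraw,
    louvain,
    run_pca,
)

from .conftest import make_matrix


def _random_norm_matrix(rng, n_genes, n_cells):
    return make_matrix(np.abs(rng.normal(1, 1, size=(n_genes, n_cells))))


class TestRunPCA:
    def test_rank_two_data_has_no_variance_beyond_pc2(self, rng):
        u = rng.normal(size=(30, 2))
        v = rng.normal(size=(2, 40))
        x = u @ v
        # shift to non-negative: the constant offset vanishes under per-gene
        # centering so the standardized matrix stays (at most) rank 2
        m = make_matrix(x - x.min())
        pca = run_pca(m, n_components=5)
        assert pca.variance_explained[2:].sum() < 1e-12

    def test_duplicated_cells_give_identical_loadings(self, rng):
        x = np.abs(rng.normal(1, 1, size=(20, 15)))
        m1 = make_matrix(x)
        m2 = make_matrix(np.hstack([x, x]))
        a = run_pca(m1, n_components=3).loadings
        b = run_pca(m2, n_components=3).loadings
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_loadings_orthonormal_and_variance_sorted(self, rng):
        m = _random_norm_matrix(rng, 25, 30)
        pca = run_pca(m, n_components=6)
        gram = pca.loadings.T @ pca.loadings
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert (np.diff(pca.variance_explained) <= 1e-12).all()

    def test_reconstruction_error_decreases_with_components(self, rng):
        # oracle: direct SVD reconstruction on the standardized 50x40 matrix
        m = _random_norm_matrix(rng, 50, 40)
        x = m.norm
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        errors = []
        for k in (2, 5, 10, 20):
            pca = run_pca(m, n_components=k)
            recon = (pca.scores @ pca.loadings.T).T
            errors.append(np.linalg.norm(z - recon))
        assert all(np.diff(errors) < 0)
        # and each error matches the optimal rank-k SVD truncation
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        svd_err = np.linalg.norm(z - (u[:, :5] * s[:5]) @ vt[:5])
        assert errors[1] == pytest.approx(svd_err, rel=1e-6)

    def test_too_many_components_rejected(self, rng):
        m = _random_norm_matrix(rng, 10, 8)
        with pytest.raises(ValueError, match="n_components"):
            run_pca(m, n_components=9)


class TestJackstraw:
    def _planted(self, seed=7, n_genes=200, n_cells=100):
        rng = np.random.default_rng(seed)
        factor = rng.normal(0, 1, n_cells)
        load = rng.normal(0, 3, n_genes)
        x = np.abs(load[:, None] * factor[None, :] + rng.normal(0, 1, (n_genes, n_cells)))
        return make_matrix(x)

    def test_planted_factor_detected(self):
        m = self._planted(seed=7)
        pca = run_pca(m, n_components=10, seed=7)
        report = jackstraw(m, pca, n_iter=100, perm_fraction=0.05,
                           alpha=0.01, seed=7)
        assert report.significant[0]
        assert not report.significant[9]

    def test_alpha_one_flags_everything(self):
        m = self._planted(seed=3)
        pca = run_pca(m, n_components=5, seed=3)
        report = jackstraw(m, pca, n_iter=20, perm_fraction=0.05,
                           alpha=1.0, seed=3)
        assert report.significant.all()
        assert (report.p_values > 0).all() and (report.p_values < 1).all()

    def test_small_iteration_count_warns(self):
        m = self._planted(seed=1, n_genes=60, n_cells=30)
        pca = run_pca(m, n_components=3, seed=1)
        with pytest.warns(UserWarning, match="unreliable"):
            jackstraw(m, pca, n_iter=5, perm_fraction=0.1, seed=1)

    def test_tiny_perm_fraction_rejected(self):
        m = self._planted(seed=1, n_genes=60, n_cells=30)
        pca = run_pca(m, n_components=3, seed=1)
        with pytest.raises(ValueError, match="permute"):
            jackstraw(m, pca, perm_fraction=1e-5, seed=1)


class TestEmbed2D:
    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(80, 5))
        a = embed_2d(pts, perplexity=10, seed=4)
        b = embed_2d(pts, perplexity=10, seed=4)
        assert np.array_equal(a.coords, b.coords)

    def test_separated_gaussians_stay_separated(self, rng):
        d = 10 / np.sqrt(5)
        pts = np.vstack([rng.normal(0, 1, (100, 5)),
                         rng.normal(d, 1, (100, 5))])
        emb = embed_2d(pts, perplexity=20, seed=0)
        labels = [0] * 100 + [1] * 100
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_perplexity_bound_enforced(self, rng):
        pts = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(pts, perplexity=10.0, seed=0)


def brute_force_jaccard_graph(coords, k):
    """Independent O(n^2) enumeration oracle for the KNN-Jaccard graph."""
    n = len(coords)
    knn = []
    for i in range(n):
        d = [(np.linalg.norm(coords[i] - coords[j]), j)
             for j in range(n) if j != i]
        d.sort()
        knn.append({j for _, j in d[:k]})
    edges = {}
    for i, j in itertools.combinations(range(n), 2):
        if j in knn[i] or i in knn[j]:
            inter = len(knn[i] & knn[j])
            if inter:
                edges[(i, j)] = inter / len(knn[i] | knn[j])
    return edges


class TestKnnJaccard:
    def test_ten_point_line_matches_enumeration(self):
        coords = np.array([[float(i), 0.0] for i in range(10)])
        graph = build_knn_jaccard(coords, k=2)
        expected = brute_force_jaccard_graph(coords, k=2)
        got = {(int(i), int(j)): w
               for (i, j), w in zip(graph.edges, graph.weights)}
        assert got == pytest.approx(expected)

    def test_coincident_points_match_enumeration(self):
        # exact distance ties resolved identically by both implementations
        coords = np.array([[0.0, 0], [0.0, 0], [5.0, 0], [5.1, 0], [10.0, 0]])
        graph = build_knn_jaccard(coords, k=2)
        got = {(int(i), int(j)): w
               for (i, j), w in zip(graph.edges, graph.weights)}
        for (i, j), w in got.items():
            assert 0 < w <= 1
        # mutual neighbours sharing one common neighbour: |{x}| / |{i,j,x}|
        assert got[(0, 1)] == pytest.approx(1 / 3)

    def test_disjoint_neighbourhoods_have_no_edge(self):
        coords = np.array([[0.0, 0], [0.1, 0], [0.2, 0],
                           [100.0, 0], [100.1, 0], [100.2, 0]])
        graph = build_knn_jaccard(coords, k=2)
        cross = [(i, j) for i, j in graph.edges if (i < 3) != (j < 3)]
        assert cross == []

    def test_weights_within_unit_interval(self, rng):
        coords = rng.normal(size=(60, 2))
        graph = build_knn_jaccard(coords, k=5)
        assert (graph.weights > 0).all() and (graph.weights <= 1).all()

    def test_k_must_be_below_cell_count(self, rng):
        with pytest.raises(ValueError, match="k="):
            build_knn_jaccard(rng.normal(size=(5, 2)), k=5)


class TestLouvain:
    def _two_blob_graph(self, rng, n=60, sep=50.0, k=8):
        coords = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                            rng.normal(sep, 1, (n // 2, 2))])
        return build_knn_jaccard(coords, k=k), [0] * (n // 2) + [1] * (n // 2)

    def _two_clique_graph(self, rng, size=12):
        # k = size-1 makes each blob a complete subgraph (a clique)
        coords = np.vstack([rng.normal(0, 0.1, (size, 2)),
                            rng.normal(50, 0.1, (size, 2))])
        return (build_knn_jaccard(coords, k=size - 1),
                [0] * size + [1] * size)

    @pytest.mark.parametrize("resolution", [0.1, 0.5, 1.0])
    def test_two_disconnected_cliques_give_two_clusters(self, rng, resolution):
        graph, truth = self._two_clique_graph(rng)
        clusters = louvain(graph, resolution=resolution, seed=0)
        assert clusters.n_clusters == 2
        assert adjusted_rand_score(truth, clusters.labels) == 1.0

    def test_tiny_resolution_limit_single_cluster_per_component(self, rng):
        graph, _ = self._two_blob_graph(rng)
        clusters = louvain(graph, resolution=1e-4, seed=0)
        assert clusters.n_clusters == 2  # graph has 2 components

    def test_six_planted_populations_recovered(self, rng):
        centers = rng.normal(0, 40, size=(6, 2))
        coords = np.vstack([c + rng.normal(0, 1, (50, 2)) for c in centers])
        truth = np.repeat(np.arange(6), 50)
        graph = build_knn_jaccard(coords, k=15)
        clusters = louvain(graph, resolution=0.1, seed=1)
        assert adjusted_rand_score(truth, clusters.labels) >= 0.9

    def test_deterministic_given_seed(self, rng):
        graph, _ = self._two_blob_graph(rng)
        a = louvain(graph, resolution=0.5, seed=5)
        b = louvain(graph, resolution=0.5, seed=5)
        assert a.labels == b.labels

    def test_order_invariance_up_to_relabel(self, rng):
        coords = np.vstack([rng.normal(0, 1, (30, 2)),
                            rng.normal(50, 1, (30, 2))])
        perm = rng.permutation(60)
        a = louvain(build_knn_jaccard(coords, k=8), resolution=0.5, seed=0)
        b = louvain(build_knn_jaccard(coords[perm], k=8), resolution=0.5, seed=0)
        a_perm = np.asarray(a.labels, dtype=object)[perm]
        assert adjusted_rand_score(a_perm.tolist(), b.labels) == 1.0

    def test_parent_class_prefix(self, rng):
        graph, _ = self._two_blob_graph(rng)
        clusters = louvain(graph, resolution=0.5, seed=0, parent_class="IN")
        assert all(lbl.startswith("IN.") for lbl in clusters.labels)

    def test_leiden_variant_runs(self, rng):
        graph, truth = self._two_blob_graph(rng)
        clusters = louvain(graph, resolution=0.05, seed=0, method="leiden")
        assert adjusted_rand_score(truth, clusters.labels) == 1.0


class TestClusterSimilarity:
    def test_self_similarity_diagonal_is_one(self, rng):
        m = _random_norm_matrix(rng, 40, 30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        sim = cluster_similarity(m, labels, labels, top_n_hvg=20)
        assert np.allclose(np.diag(sim.values.loc[["a", "b", "c"],
                                                  ["a", "b", "c"]]), 1.0)

    def test_small_cluster_flagged(self, rng):
        m = _random_norm_matrix(rng, 20, 11)
        labels = ["a"] * 10 + ["b"]
        sim = cluster_similarity(m, labels, labels, top_n_hvg=10)
        assert "b" in sim.small_clusters

    def test_shared_structure_orders_correlations(self, rng):
        # two clusters sharing half their marker structure correlate less
        # than within-type but more than an unrelated cluster
        n = 40
        base = np.abs(rng.normal(1, 0.1, size=(60, 3 * n)))
        base[:10, :n] += 3          # markers of cluster a
        base[:5, n:2 * n] += 3      # half shared with cluster b
        base[10:15, n:2 * n] += 3
        base[20:30, 2 * n:] += 3    # unrelated cluster c
        noise = np.abs(rng.normal(0, 0.3, base.shape))
        m = make_matrix(base + noise)
        labels = ["a"] * n + ["b"] * n + ["c"] * n
        sim = cluster_similarity(m, labels, labels, top_n_hvg=60).values
        assert sim.loc["a", "a"] > sim.loc["a", "b"] > sim.loc["a", "c"]


class TestCrossTabulate:
    def test_identical_assignments_are_diagonal(self):
        labels = ["x", "y", "x", "z"]
        table = cross_tabulate(labels, labels)
        off_diag = table.to_numpy().sum() - np.diag(
            table.loc[["x", "y", "z"], ["x", "y", "z"]]).sum()
        assert off_diag == 0

    def test_total_conserved(self, rng):
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 4, 50)
        assert cross_tabulate(a, b).to_numpy().sum() == 50

    def test_margins_equal_cluster_sizes(self, rng):
        a = rng.integers(0, 3, 80)
        b = rng.integers(0, 2, 80)
        table = cross_tabulate(a, b)
        for lbl in np.unique(a):
            assert table.loc[lbl].sum() == (a == lbl).sum()
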