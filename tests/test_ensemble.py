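import numpy as np
import pytest

from depf.ensemble import (
    bipartite_spectral,
    community_partition,
    generate_ensemble,
    read_ensemble,
    select_representatives,
    sparse_affinity,
    write_ensemble,
)
from depf.metrics import ari
from depf.simulate import simulate_latent_blobs


class TestRepresentatives:
    def test_all_cells_when_p_equals_n_random_only(self):
        X, _ = simulate_latent_blobs(25, dim=3, k=2, seed=0)
        reps = select_representatives(X, p=25, mix_frac=0.0, seed=1)
        # a permutation of the cells themselves
        sorted_reps = reps.points[np.lexsort(reps.points.T)]
        sorted_X = X[np.lexsort(X.T)]
        np.testing.assert_allclose(sorted_reps, sorted_X)

    def test_single_kmeans_rep_is_near_centroid(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3))
        reps = select_representatives(X, p=1, mix_frac=1.0, seed=3)
        assert np.linalg.norm(reps.points[0] - X.mean(0)) < 0.5

    def test_deterministic(self):
        X, _ = simulate_latent_blobs(40, dim=3, k=2, seed=1)
        r1 = select_representatives(X, p=10, mix_frac=0.5, seed=5)
        r2 = select_representatives(X, p=10, mix_frac=0.5, seed=5)
        np.testing.assert_array_equal(r1.points, r2.points)

    def test_p_out_of_range(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            select_representatives(X, p=6)


class TestSparseAffinity:
    def test_coincident_point_has_unit_affinity(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        reps = select_representatives(X, p=2, mix_frac=0.0, seed=0)
        S = sparse_affinity(X, reps, K=1, sigma=1.0).toarray()
        assert S.max() == pytest.approx(1.0)

    def test_full_K_equals_dense_kernel(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 3))
        reps = select_representatives(X, p=5, mix_frac=0.0, seed=1)
        S = sparse_affinity(X, reps, K=5, sigma=2.0).toarray()
        d2 = ((X[:, None, :] - reps.points[None, :, :]) ** 2).sum(-1)
        np.testing.assert_allclose(S, np.exp(-d2 / (2 * 2.0**2)), atol=1e-12)

    def test_matches_brute_force_k_nearest(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 4))
        reps = select_representatives(X, p=5, mix_frac=0.0, seed=2)
        K, sigma = 3, 1.5
        S = sparse_affinity(X, reps, K=K, sigma=sigma).toarray()
        expected = np.zeros_like(S)
        for i in range(20):
            d = np.linalg.norm(X[i] - reps.points, axis=1)
            nearest = sorted(range(5), key=lambda j: (d[j], j))[:K]
            for j in nearest:
                expected[i, j] = np.exp(-d[j] ** 2 / (2 * sigma**2))
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_each_row_has_K_nonzeros(self):
        X, _ = simulate_latent_blobs(30, dim=3, k=2, seed=3)
        reps = select_representatives(X, p=10, mix_frac=0.5, seed=0)
        S = sparse_affinity(X, reps, K=4)
        assert (np.diff(S.indptr) == 4).all()


def dense_spectral_oracle(X, k, seed):
    """Independent normalized-cut spectral clustering on the full kernel."""
    from scipy.spatial.distance import pdist, squareform
    from sklearn.cluster import KMeans

    D2 = squareform(pdist(X)) ** 2
    sigma = np.sqrt(D2).mean()
    W = np.exp(-D2 / (2 * sigma**2))
    deg = W.sum(1)
    L = (W / np.sqrt(deg)[:, None]) / np.sqrt(deg)[None, :]
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, -k:]
    U = U / np.maximum(np.linalg.norm(U, axis=1, keepdims=True), 1e-12)
    return KMeans(k, n_init=10, random_state=seed).fit_predict(U)


class TestBipartiteSpectral:
    def test_separable_blobs_recovered_exactly(self):
        X, labels = simulate_latent_blobs(60, dim=4, k=2, separation=10, seed=5)
        reps = select_representatives(X, p=20, mix_frac=0.5, seed=1)
        S = sparse_affinity(X, reps, K=5)
        part = bipartite_spectral(S, k=2, seed=0)
        assert ari(labels, part.labels) == 1.0

    def test_reduces_to_dense_spectral_clustering(self):
        for seed in range(3):
            X, _ = simulate_latent_blobs(30, dim=4, k=3, separation=6, seed=seed)
            reps = select_representatives(X, p=30, mix_frac=0.0, seed=seed)
            S = sparse_affinity(X, reps, K=30)
            ours = bipartite_spectral(S, k=3, seed=seed).labels
            oracle = dense_spectral_oracle(X, 3, seed)
            assert ari(ours, oracle) >= 0.99

    def test_deterministic(self):
        X, _ = simulate_latent_blobs(40, dim=3, k=2, separation=5, seed=7)
        reps = select_representatives(X, p=15, mix_frac=0.5, seed=2)
        S = sparse_affinity(X, reps, K=5)
        l1 = bipartite_spectral(S, k=2, seed=3).labels
        l2 = bipartite_spectral(S, k=2, seed=3).labels
        np.testing.assert_array_equal(l1, l2)


class TestCommunityPartition:
    def test_disconnected_cliques_give_two_communities(self):
        # two tight, far-apart blobs whose kNN graphs are complete cliques
        X, labels = simulate_latent_blobs(20, dim=3, k=2, separation=100, seed=1)
        knn = int(np.bincount(labels).min()) - 1  # neighbors stay in-blob
        for method in ("louvain", "leiden"):
            part = community_partition(X, method=method, resolution=0.5,
                                       knn=knn, seed=0)
            assert part.k == 2
            assert ari(labels, part.labels) == 1.0

    def test_resolution_increases_cluster_count(self):
        X, _ = simulate_latent_blobs(120, dim=4, k=3, separation=3, seed=2)
        mean_k = []
        for res in (0.3, 3.0):
            ks = [
                community_partition(X, "leiden", resolution=res, knn=10, seed=s).k
                for s in range(5)
            ]
            mean_k.append(np.mean(ks))
        assert mean_k[1] >= mean_k[0]

    def test_deterministic(self):
        X, _ = simulate_latent_blobs(50, dim=3, k=2, separation=4, seed=3)
        for method in ("louvain", "leiden"):
            l1 = community_partition(X, method, 1.0, knn=8, seed=11).labels
            l2 = community_partition(X, method, 1.0, knn=8, seed=11).labels
            np.testing.assert_array_equal(l1, l2)

    def test_bad_resolution_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            community_partition(X, "leiden", resolution=0.0, knn=3)


class TestGenerateEnsemble:
    def test_partition_counts_and_grouping(self, blob_latent):
        Z, _ = blob_latent
        ens = generate_ensemble(Z, k=3, T=10, seed=0, p=60)
        assert len(ens.partitions) == 30
        groups = ens.by_subspace()
        assert all(len(g) == 10 for g in groups.values())
        ens1 = generate_ensemble(Z, k=3, T=1, seed=0, p=60)
        assert len(ens1.partitions) == Z.d

    def test_reproducible_and_diverse(self, blob_latent):
        Z, _ = blob_latent
        e1 = generate_ensemble(Z, k=3, T=3, seed=4, p=60)
        e2 = generate_ensemble(Z, k=3, T=3, seed=4, p=60)
        for a, b in zip(e1.partitions, e2.partitions):
            np.testing.assert_array_equal(a.labels, b.labels)
        # run-to-run label vectors are not all identical
        stack = np.vstack([p.labels for p in e1.partitions])
        assert len({tuple(r) for r in stack}) > 1

    def test_export_import_roundtrip(self, tmp_path, blob_latent):
        Z, _ = blob_latent
        ens = generate_ensemble(Z, k=3, T=2, seed=1, p=60)
        lp, mp = str(tmp_path / "labels.csv"), str(tmp_path / "meta.json")
        write_ensemble(ens, lp, mp)
        back = read_ensemble(lp, mp)
        assert back.D == ens.D and back.T == ens.T
        for a, b in zip(ens.partitions, back.partitions):
            np.testing.assert_array_equal(a.labels, b.labels)
            assert (a.subspace_index, a.run_index) == (b.subspace_index, b.run_index)
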