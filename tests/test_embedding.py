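"""Dunn's Index (with brute-force oracle), the clustering sweep, and
DI-based model selection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from preictal_scout.embedding import (ClusterSolution, EmbeddingConfig,
                                      cluster_all, dunn_index, embed_grid,
                                      select_best)

TINY = EmbeddingConfig(n_neighbors_grid=(10, 15), min_dist_grid=(0.1, 0.5),
                       hdbscan_min_cluster_size=10, rng_seed=42)


def dunn_bruteforce(points, labels):
    """O(n^2) enumeration of all pairwise distances (independent oracle)."""
    ids = [c for c in np.unique(labels) if c >= 0]
    if len(ids) < 2 or min((labels == c).sum() for c in ids) < 2:
        return np.nan
    inter, diam = np.inf, 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if labels[i] < 0 or labels[j] < 0:
                continue
            d = float(np.linalg.norm(points[i] - points[j]))
            if labels[i] == labels[j]:
                diam = max(diam, d)
            else:
                inter = min(inter, d)
    if inter == 0:
        return 0.0
    return inter / diam if diam > 0 else np.inf


class TestDunnIndex:
    def test_two_pair_clusters_hand_computed(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 10], [0, 0, 11.0]])
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(pts, labels) == pytest.approx(9.0)

    def test_overlapping_identical_clusters_zero(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1.0]])
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(pts, labels) == 0.0

    def test_undefined_cases(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.isnan(dunn_index(pts, np.zeros(10)))          # 1 cluster
        labels = np.array([0] * 9 + [1])
        assert np.isnan(dunn_index(pts, labels))                # singleton
        labels = np.array([-1] * 8 + [0, 1])
        assert np.isnan(dunn_index(pts, labels))                # noise only

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(6, 51)
            k = rng.integers(2, 5)
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            expect = dunn_bruteforce(pts, labels)
            got = dunn_index(pts, labels)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        base = dunn_index(pts, labels)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = pts @ q.T + rng.normal(size=3)
            assert dunn_index(moved, labels) == pytest.approx(base, abs=1e-9)


def blobs(rng, centers, n_each=60, scale=0.5):
    pts = np.vstack([c + scale * rng.normal(size=(n_each, len(c)))
                     for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_each)
    return pts, labels


class TestEmbedGrid:
    def test_grid_size_and_shape(self, rng):
        x = rng.normal(size=(120, 6))
        embs = embed_grid(x, TINY)
        assert len(embs) == 4
        assert all(e.shape == (120, 3) for _, e in embs)

    def test_seed_reproducibility(self, rng):
        x = rng.normal(size=(80, 5))
        e1 = embed_grid(x, TINY)
        e2 = embed_grid(x, TINY)
        for (p1, a), (p2, b) in zip(e1, e2):
            assert p1 == p2
            np.testing.assert_array_equal(a, b)

    def test_neighbor_grid_clipped_with_warning(self, rng):
        x = rng.normal(size=(30, 4))
        cfg = EmbeddingConfig(n_neighbors_grid=(10, 100),
                              min_dist_grid=(0.1,))
        with pytest.warns(UserWarning):
            embs = embed_grid(x, cfg)
        assert all(p[0] < 30 for p, _ in embs)


class TestClusterAll:
    def test_ten_solutions_returned(self, rng):
        pts, _ = blobs(rng, [(0, 0, 0), (8, 0, 0)])
        sols = cluster_all(pts, (10, 0.1), TINY)
        assert len(sols) == 10
        methods = [s.method for s in sols]
        assert methods.count("hdbscan") == 1
        assert sum(m.startswith("kmeans") for m in methods) == 3

    def test_separated_blobs_recovered(self, rng):
        pts, truth = blobs(rng, [(0, 0, 0), (10, 0, 0), (0, 10, 0)],
                           scale=0.3)
        sols = cluster_all(pts, (10, 0.1), TINY)
        km3 = next(s for s in sols if s.method == "kmeans_k3")
        assert adjusted_rand_score(truth, km3.labels) == 1.0
        assert km3.dunn_index > 1.0

    def test_single_blob_hdbscan_undefined(self, rng):
        pts = rng.normal(size=(100, 3))
        sols = cluster_all(pts, (10, 0.1), TINY)
        hdb = next(s for s in sols if s.method == "hdbscan")
        if hdb.n_clusters <= 1:
            assert np.isnan(hdb.dunn_index)


class TestSelectBest:
    def _results(self, entries):
        return [(p, e, sols) for p, e, sols in entries]

    def test_max_di_selected(self, rng):
        e1, e2 = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        s_low = ClusterSolution(np.zeros(20, int), "kmeans_k2", (10, 0.1), 0.5)
        s_high = ClusterSolution(np.zeros(20, int), "gmm_k2", (20, 0.1), 2.0)
        emb, sol = select_best(self._results(
            [((10, 0.1), e1, [s_low]), ((20, 0.1), e2, [s_high])]),
            TINY)
        assert sol.method == "gmm_k2"
        assert emb is e2

    def test_tie_keeps_first_in_order(self, rng):
        e1, e2 = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        s1 = ClusterSolution(np.zeros(20, int), "kmeans_k2", (10, 0.1), 1.0)
        s2 = ClusterSolution(np.zeros(20, int), "gmm_k2", (20, 0.1), 1.0)
        _, sol = select_best(self._results(
            [((10, 0.1), e1, [s1]), ((20, 0.1), e2, [s2])]), TINY)
        assert sol.method == "kmeans_k2"

    def test_dbscan_fallback_on_undefined_grid(self, rng):
        pts, _ = blobs(rng, [(0, 0, 0), (12, 0, 0)], n_each=40, scale=0.3)
        undef = ClusterSolution(None, "kmeans_k2", (10, 0.1), np.nan)
        _, sol = select_best(self._results([((10, 0.1), pts, [undef])]),
                             TINY)
        assert sol.method.startswith("dbscan")
        assert sol.n_clusters >= 2
        assert np.isfinite(sol.dunn_index)

    def test_degenerate_cloud_flagged_unclustered(self):
        pts = np.zeros((25, 3))
        undef = ClusterSolution(None, "kmeans_k2", (10, 0.1), np.nan)
        emb, sol = select_best(self._results([((10, 0.1), pts, [undef])]),
                               TINY)
        assert sol.unclustered
        assert np.all(sol.labels == 0)
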