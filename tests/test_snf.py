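import numpy as np
import pytest

from omicsfuse import (
    AffinityNetwork,
    DataError,
    build_affinity,
    cluster_fused,
    rsnf_rank,
    snf_fuse,
)
from omicsfuse.io import OmicsLayer
from omicsfuse.snf import _full_normalize, eigengap_n_clusters, spectral_labels
from conftest import make_layer


def two_block_layer(name, n=40, p=20, sep=6.0, noise=1.0, seed=0):
    rng = np.random.RandomState(seed)
    x = noise * rng.randn(n, p)
    x[n // 2 :] += sep
    return make_layer(name, n, p, values=x)


def block_affinity(n=40, b=20, value=0.7):
    w = np.zeros((n, n))
    w[:b, :b] = value
    w[b:, b:] = value
    np.fill_diagonal(w, 0.0)
    return AffinityNetwork(w, [f"s{i}" for i in range(n)], b - 1, 0.5)


def block_contrast(m, n):
    """Mean within-block minus mean between-block similarity (diag excluded)."""
    half = n // 2
    within = np.concatenate(
        [m[:half, :half][~np.eye(half, dtype=bool)], m[half:, half:][~np.eye(half, dtype=bool)]]
    ).mean()
    between = m[:half, half:].mean()
    return within - between


class TestBuildAffinity:
    def test_identical_samples_maximal_similarity(self):
        x = np.vstack([np.ones(5), np.ones(5), np.zeros(5), 2 + np.zeros(5)])
        layer = make_layer("A", 4, 5, values=x)
        net = build_affinity(layer, k=2)
        assert net.matrix[0, 1] == pytest.approx(1.0)
        assert net.matrix[0, 2] < 1.0

    def test_two_tight_clusters_within_exceeds_between(self):
        layer = two_block_layer("A", sep=10.0, noise=0.5, seed=1)
        m = build_affinity(layer, k=5).matrix
        half = 20
        within = m[:half, :half][~np.eye(half, dtype=bool)].mean()
        between = m[:half, half:].mean()
        assert within > 10 * between

    def test_feature_scaling_preserves_similarity_order(self):
        layer = two_block_layer("A", seed=2)
        scaled = make_layer("A", 40, 20, values=layer.values * 3.7)
        a = build_affinity(layer, k=5).matrix
        b = build_affinity(scaled, k=5).matrix
        iu = np.triu_indices(40, 1)
        assert (np.argsort(a[iu]) == np.argsort(b[iu])).all()

    def test_symmetric_zero_diagonal(self):
        net = build_affinity(two_block_layer("A", seed=3), k=7)
        np.testing.assert_allclose(net.matrix, net.matrix.T)
        assert np.all(np.diag(net.matrix) == 0)

    def test_k_capped_and_small_n_errors(self):
        layer = make_layer("A", 5, 3, seed=4)
        assert build_affinity(layer, k=20).k_neighbors == 4
        with pytest.raises(DataError):
            build_affinity(make_layer("A", 2, 3, seed=4))


class TestSnfFuse:
    def test_identical_copy_is_fixed_point_on_block_network(self):
        net = block_affinity()
        p0 = _full_normalize(net.matrix)
        p0 = (p0 + p0.T) / 2
        fused = snf_fuse([net, block_affinity()], k=19, t=20).matrix
        assert np.abs(fused - p0).max() < 1e-6

    def test_t_zero_returns_average_of_normalized_inputs(self):
        n1 = build_affinity(two_block_layer("A", seed=5), k=5)
        n2 = build_affinity(two_block_layer("B", seed=6), k=5)
        fused = snf_fuse([n1, n2], k=5, t=0).matrix
        p1, p2 = _full_normalize(n1.matrix), _full_normalize(n2.matrix)
        expected = (p1 + p2) / 2
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(fused, expected, atol=1e-12)

    def test_fused_symmetric_nonnegative(self):
        n1 = build_affinity(two_block_layer("A", noise=2.0, seed=7), k=8)
        n2 = build_affinity(two_block_layer("B", noise=2.0, seed=8), k=8)
        fused = snf_fuse([n1, n2], k=8, t=10).matrix
        np.testing.assert_allclose(fused, fused.T, atol=1e-12)
        assert (fused >= 0).all()

    def test_fusion_sharpens_two_block_structure(self):
        n1 = build_affinity(two_block_layer("A", sep=2.0, noise=1.5, seed=9), k=10)
        n2 = build_affinity(two_block_layer("B", sep=2.0, noise=1.5, seed=10), k=10)
        fused = snf_fuse([n1, n2], k=10, t=10).matrix
        c_fused = block_contrast(fused / fused.max(), 40)
        c1 = block_contrast(_full_normalize(n1.matrix) / _full_normalize(n1.matrix).max(), 40)
        c2 = block_contrast(_full_normalize(n2.matrix) / _full_normalize(n2.matrix).max(), 40)
        assert c_fused > c1 and c_fused > c2

    def test_sample_mismatch_errors(self):
        n1 = build_affinity(two_block_layer("A", seed=1), k=5)
        layer = two_block_layer("B", seed=2)
        layer.sample_ids[0] = "other"
        n2 = build_affinity(OmicsLayer("B", layer.sample_ids, layer.feature_ids, layer.values), k=5)
        with pytest.raises(DataError):
            snf_fuse([n1, n2])


class TestClusterFused:
    def test_perfect_two_block_recovery(self):
        fused = snf_fuse([block_affinity(), block_affinity()], k=19, t=5)
        fused = cluster_fused(fused, 2, seed=0)
        labels = fused.cluster_labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_eigengap_detects_three_blocks(self):
        n = 45
        w = np.zeros((n, n))
        for i in range(3):
            w[15 * i : 15 * (i + 1), 15 * i : 15 * (i + 1)] = 0.8
        w += 0.01 * np.random.RandomState(0).rand(n, n)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        assert eigengap_n_clusters(w, range(2, 6)) == 3

    def test_permutation_equivariance(self):
        w = block_affinity().matrix + 0.01 * np.random.RandomState(1).rand(40, 40)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = spectral_labels(w, 2, seed=0)
        perm = np.random.RandomState(2).permutation(40)
        labels_perm = spectral_labels(w[np.ix_(perm, perm)], 2, seed=0)
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_too_many_clusters_error(self):
        fused = snf_fuse([block_affinity(8, 4), block_affinity(8, 4)], k=3, t=2)
        with pytest.raises(DataError):
            cluster_fused(fused, 8)


class TestRsnfRank:
    def test_partition_encoding_feature_is_top_with_nmi_one(self):
        rng = np.random.RandomState(3)
        n = 30
        labels = np.repeat([0, 1], n // 2)
        x = rng.randn(n, 10)
        x[:, 4] = labels * 5.0  # exactly encodes the partition
        layer = make_layer("A", n, 10, values=x)
        ranked = rsnf_rank(layer, labels, k=5, seed=0)
        assert ranked.feature_ids[0] == "A:f4"
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_noise_features_rank_low(self):
        rng = np.random.RandomState(4)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        x = rng.randn(n, 20)
        x[:, 0] = labels * 4.0 + 0.1 * rng.randn(n)
        layer = make_layer("A", n, 20, values=x)
        ranked = rsnf_rank(layer, labels, k=8, seed=1)
        assert ranked.feature_ids[0] == "A:f0"
        # the planted feature beats at least 95% of the noise features
        noise_scores = [
            s for f, s in zip(ranked.feature_ids, ranked.scores) if f != "A:f0"
        ]
        top_score = dict(zip(ranked.feature_ids, ranked.scores))["A:f0"]
        assert np.mean([top_score > s for s in noise_scores]) >= 0.95

    def test_duplicated_feature_identical_scores_adjacent(self):
        rng = np.random.RandomState(5)
        n = 24
        labels = np.repeat([0, 1], n // 2)
        x = rng.randn(n, 6)
        x[:, 3] = x[:, 2]
        layer = make_layer("A", n, 6, values=x)
        ranked = rsnf_rank(layer, labels, k=5, seed=2)
        pos = {f: i for i, f in enumerate(ranked.feature_ids)}
        by_id = dict(zip(ranked.feature_ids, ranked.scores))
        assert by_id["A:f2"] == by_id["A:f3"]
        assert abs(pos["A:f2"] - pos["A:f3"]) == 1

    def test_single_cluster_errors(self):
        layer = make_layer("A", 10, 4, seed=6)
        with pytest.raises(DataError):
            rsnf_rank(layer, np.zeros(10, dtype=int))
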