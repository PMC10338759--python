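"""CCE core: distances, similarities, matrix powers, centers, Ncut, sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from canopycce import (CCEConfig, ConnectionCenterClustering, SuperPointSet,
                       assign_points, build_distance_matrix, cce_sweep,
                       connectivity_power, find_centers, gaussian_similarity,
                       normalize_similarity, normalized_cut)

S2x2 = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])


class TestDistanceMatrix:
    def test_coincident_points_zero(self):
        sp = SuperPointSet(np.zeros((2, 3)), [3, 5], [0, 0, 0, 1, 1, 1, 1, 1])
        D = build_distance_matrix(sp, vr=0.5)
        np.testing.assert_allclose(D, 0.0)

    def test_weighted_hand_value(self):
        sp = SuperPointSet([[0, 0, 0], [3, 4, 0]], [1, 2], [0, 1, 1])
        D = build_distance_matrix(sp, vr=0.7)
        assert D[0, 1] == pytest.approx(10.0)  # 1*2*sqrt(9+16)
        assert D[1, 0] == pytest.approx(10.0)

    def test_vertical_correction_hand_value(self):
        D = build_distance_matrix(np.array([[0, 0, 0], [0, 0, 6.0]]), vr=1 / 6)
        assert D[0, 1] == pytest.approx(np.sqrt(6.0))

    def test_weight_mode_none_ignores_weights(self):
        sp = SuperPointSet([[0, 0, 0], [3, 4, 0]], [5, 7], np.zeros(12, dtype=int))
        D = build_distance_matrix(sp, vr=1.0, weight_mode="none")
        assert D[0, 1] == pytest.approx(5.0)


class TestSimilarity:
    def test_zero_distance_unit_similarity(self):
        S = gaussian_similarity(np.zeros((3, 3)), sigma=30.0)
        np.testing.assert_allclose(S, 1.0)

    def test_d_equals_sigma(self):
        D = np.array([[0.0, 30.0], [30.0, 0.0]])
        S = gaussian_similarity(D, sigma=30.0)
        assert S[0, 1] == pytest.approx(np.exp(-1.0))

    def test_monotone_decreasing(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        S = gaussian_similarity(D, sigma=2.0)
        assert S[0, 1] > S[0, 2]

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_similarity(np.zeros((2, 2)), sigma=0.0)


class TestNormalization:
    def test_identity_stays_identity(self):
        S, deg = normalize_similarity(np.eye(4))
        np.testing.assert_allclose(S, np.eye(4))
        np.testing.assert_allclose(deg, 1.0)

    def test_two_point_hand_value(self):
        S, deg = normalize_similarity(np.array([[1.0, 0.5], [0.5, 1.0]]))
        np.testing.assert_allclose(S, S2x2)
        np.testing.assert_allclose(deg, [1.5, 1.5])

    def test_two_point_rows_sum_to_one(self, rng):
        s = rng.uniform(0.01, 0.99)
        S, _ = normalize_similarity(np.array([[1.0, s], [s, 1.0]]))
        np.testing.assert_allclose(S.sum(axis=1), 1.0)


class TestConnectivityPower:
    def test_k1_is_identity_operation(self):
        np.testing.assert_array_equal(connectivity_power(S2x2, 1), S2x2)

    def test_k2_hand_value(self):
        np.testing.assert_allclose(connectivity_power(S2x2, 2),
                                   [[5 / 9, 4 / 9], [4 / 9, 5 / 9]])

    def test_large_k_eigen_limit(self):
        # eigenvalues 1 and 1/3: S^k -> ones/2
        np.testing.assert_allclose(connectivity_power(S2x2, 60), 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_multiplication(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 20)
        X = rng.uniform(0, 10, size=(n, 3))
        D = build_distance_matrix(X, vr=0.5)
        S, _ = normalize_similarity(gaussian_similarity(D, sigma=8.0))
        for k in (2, 3, 5, 8):
            np.testing.assert_allclose(connectivity_power(S, k),
                                       oracles.naive_matrix_power(S, k), atol=1e-10)


class TestCentersAndAssignment:
    def test_k1_every_point_is_center(self, rng):
        X = rng.uniform(0, 10, size=(12, 3))
        D = build_distance_matrix(X, vr=1.0)
        S, _ = normalize_similarity(gaussian_similarity(D, sigma=5.0))
        assert list(find_centers(S)) == list(range(12))

    def test_two_point_k2_both_centers(self):
        S2 = connectivity_power(S2x2, 2)
        assert list(find_centers(S2)) == [0, 1]

    def test_exact_tie_lower_index_wins(self):
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert list(find_centers(S)) == [0]

    def test_all_points_centers_assign_to_self(self, rng):
        X = rng.uniform(0, 10, size=(8, 3))
        D = build_distance_matrix(X, vr=1.0)
        S, _ = normalize_similarity(gaussian_similarity(D, sigma=5.0))
        res = assign_points(S, np.arange(8))
        np.testing.assert_array_equal(res.assignment, np.arange(8))

    def test_one_center_takes_all(self):
        S2 = connectivity_power(S2x2, 2)
        res = assign_points(S2, np.array([1]))
        np.testing.assert_array_equal(res.assignment, [0, 0])

    def test_two_blob_assignment_brute_force(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (3, 3)), rng.normal(8, 0.3, (3, 3))])
        D = build_distance_matrix(X, vr=1.0)
        S, _ = normalize_similarity(gaussian_similarity(D, sigma=3.0))
        Sk = connectivity_power(S, 4)
        centers = find_centers(Sk)
        res = assign_points(Sk, centers)
        expected = oracles.brute_force_assignment(Sk, list(centers))
        np.testing.assert_array_equal(res.assignment, expected)
        blob = res.assignment[:3]
        assert len(set(blob)) == 1 and len(set(res.assignment[3:])) == 1
        assert res.assignment[0] != res.assignment[3]


class TestNormalizedCut:
    def test_single_cluster_zero(self):
        assert normalized_cut(S2x2, np.zeros(2, dtype=int)) == 0.0

    def test_block_diagonal_zero(self):
        S = np.block([[np.ones((2, 2)), np.zeros((2, 2))],
                      [np.zeros((2, 2)), np.ones((2, 2))]])
        assert normalized_cut(S, np.array([0, 0, 1, 1])) == 0.0

    def test_singleton_partition_hand_value(self):
        assert normalized_cut(S2x2, np.array([0, 1])) == pytest.approx(2 / 3)


class TestSweep:
    def test_single_superpoint(self):
        sp = SuperPointSet([[0, 0, 10.0]], [1], [0])
        results = cce_sweep(sp, CCEConfig())
        assert len(results) == 1
        assert results[0].m == 1 and results[0].k == 1

    def test_two_distant_points_micro_to_macro(self):
        sp = SuperPointSet([[0, 0, 0], [10.0, 0, 0]], [1, 1], [0, 1])
        results = cce_sweep(sp, CCEConfig(sigma=30.0))
        assert results[0].m == 2  # micro scale: both centers
        assert results[-1].m == 1  # macro scale: one connected component

    @pytest.mark.parametrize("seed", range(5))
    def test_large_k_single_perron_center(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        X = rng.uniform(0, 5, size=(n, 3))
        sp = SuperPointSet(X, np.ones(n, dtype=int), np.arange(n))
        config = CCEConfig(sigma=30.0)
        results = cce_sweep(sp, config)
        assert results[-1].m == 1
        # Perron argmax oracle via eigen-decomposition
        D = build_distance_matrix(sp, config.vr)
        S, _ = normalize_similarity(gaussian_similarity(D, config.sigma))
        w, v = np.linalg.eigh(S)
        lead = np.abs(v[:, np.argmax(w)])
        assert results[-1].centers[0] == np.argmax(lead)

    def test_symmetry_preserved_through_sweep(self, rng):
        X = rng.uniform(0, 5, size=(20, 3))
        sp = SuperPointSet(X, np.ones(20, dtype=int), np.arange(20))
        D = build_distance_matrix(sp, 1 / 6)
        assert np.abs(D - D.T).max() < 1e-12
        S_t = gaussian_similarity(D, 30.0)
        assert np.abs(S_t - S_t.T).max() < 1e-12
        S, _ = normalize_similarity(S_t)
        assert np.abs(S - S.T).max() < 1e-12
        Sk = connectivity_power(S, 8)
        assert np.abs(Sk - Sk.T).max() < 1e-12

    def test_two_crown_segment_recovers_blobs(self):
        rng = np.random.default_rng(4)
        blobs = [rng.normal(0, 0.8, (30, 3)) * [1, 1, 2] + [c, 0, 12]
                 for c in (0.0, 6.0)]
        X = np.vstack(blobs)
        sp = SuperPointSet(X, np.ones(60, dtype=int), np.arange(60))
        # sigma on the scale of the (unweighted) meter distances
        results = cce_sweep(sp, CCEConfig(sigma=3.0))
        good = [r for r in results if r.m == 2]
        assert good, "no scale produced two clusters"
        r = good[0]
        first, second = r.assignment[:30], r.assignment[30:]
        purity = max(np.mean(first == first[0]), np.mean(first != first[0]))
        assert purity >= 0.95
        assert (np.bincount(first).argmax() != np.bincount(second).argmax())


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_centers_and_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 16))
        X = rng.uniform(0, 10, size=(n, 3))
        w = rng.integers(1, 10, size=n)
        sp = SuperPointSet(X, w, np.repeat(np.arange(n), w))
        D = build_distance_matrix(sp, vr=1 / 6)
        S, _ = normalize_similarity(gaussian_similarity(D, sigma=30.0))
        for k in (1, 2, 4, 8):
            Sk = oracles.naive_matrix_power(S, k)
            centers = find_centers(Sk)
            np.testing.assert_array_equal(centers, oracles.brute_force_centers(Sk))
            if centers.size:
                res = assign_points(Sk, centers)
                np.testing.assert_array_equal(
                    res.assignment, oracles.brute_force_assignment(Sk, list(centers)))


def test_clusterer_estimator_separates_two_crowns():
    rng = np.random.default_rng(6)
    crowns = []
    for cx in (0.0, 6.0):
        d = 8.0 * np.cbrt(rng.uniform(size=150))
        r = 1.5 * (d / 8.0) * np.sqrt(rng.uniform(size=150))
        az = rng.uniform(0, 2 * np.pi, 150)
        crowns.append(np.c_[cx + r * np.cos(az), r * np.sin(az), 16.0 - d])
    X = np.vstack(crowns)
    est = ConnectionCenterClustering().fit(X)
    assert est.n_clusters_ == 2
    first = est.labels_[:150]
    purity = max(np.mean(first == 0), np.mean(first == 1))
    assert purity >= 0.95


def test_config_validation():
    with pytest.raises(ValueError):
        CCEConfig(vr=0.0)
    with pytest.raises(ValueError):
        CCEConfig(sigma=-1.0)
    with pytest.raises(ValueError):
        CCEConfig(weight_mode="other")
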