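"""DTW correctness against exhaustive enumeration, k-means behavior,
validity indices and bootstrap stability."""

import itertools

import numpy as np
import pytest

from progsub import cluster as cl


def brute_force_dtw(S, S2):
    """Exhaustive minimum over all admissible warping paths (oracle)."""
    S = np.atleast_2d(np.asarray(S, float).T).T
    if S.ndim == 1:
        S = S[:, None]
    S2 = np.asarray(S2, float)
    if S2.ndim == 1:
        S2 = S2[:, None]
    n, m = len(S), len(S2)
    best = [np.inf]

    def cost(i, j):
        return float(np.linalg.norm(S[i] - S2[j]))

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                walk(ii, jj, acc + cost(ii, jj))

    walk(0, 0, cost(0, 0))
    return best[0]


class TestDTW:
    def test_identity_is_zero(self, rng):
        S = rng.normal(size=(7, 3))
        assert cl.dtw(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_length_one_sequences(self):
        assert cl.dtw([[1.0, 2.0]], [[4.0, 6.0]]) == pytest.approx(5.0)

    def test_classic_warping_example(self):
        # [1,2,3] vs [1,2,2,3]: the repeated 2 aligns at zero cost
        assert cl.dtw([1, 2, 3], [1, 2, 2, 3]) == pytest.approx(0.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(60):
            n, m = rng.integers(1, 7, size=2)
            d = int(rng.integers(1, 4))
            S, S2 = rng.normal(size=(n, d)), rng.normal(size=(m, d))
            assert cl.dtw(S, S2) == pytest.approx(brute_force_dtw(S, S2),
                                                  abs=1e-10)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            S = rng.normal(size=(int(rng.integers(1, 9)), 2))
            S2 = rng.normal(size=(int(rng.integers(1, 9)), 2))
            d = cl.dtw(S, S2)
            assert d >= 0
            assert d == pytest.approx(cl.dtw(S2, S), abs=1e-12)

    def test_path_is_admissible(self, rng):
        S, S2 = rng.normal(size=(6, 2)), rng.normal(size=(9, 2))
        dist, path = cl.dtw(S, S2, return_path=True)
        assert path[0] == (0, 0)
        assert path[-1] == (5, 8)
        steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(path, path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}
        # the path's cumulative cost equals the reported distance
        total = sum(float(np.linalg.norm(S[i] - S2[j])) for i, j in path)
        assert total == pytest.approx(dist, abs=1e-10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cl.dtw(np.empty((0, 2)), np.ones((3, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cl.dtw(np.ones((3, 2)), np.ones((3, 4)))


def _two_bundles(rng, n_per=12, length=(8, 14)):
    seqs, labels = [], []
    for c, center in enumerate((-4.0, 4.0)):
        for _ in range(n_per):
            T = int(rng.integers(*length))
            seqs.append(center + rng.normal(scale=0.3, size=(T, 3)))
            labels.append(c)
    return seqs, np.asarray(labels)


class TestTsKmeans:
    def test_k_equals_n_gives_zero_objective(self, rng):
        seqs = [rng.normal(size=(5, 2)) for _ in range(6)]
        model = cl.ts_kmeans(seqs, K=6, seed=0, n_init=1)
        assert model.objective == pytest.approx(0.0, abs=1e-9)

    def test_recovers_two_well_separated_bundles(self, rng):
        from sklearn.metrics import adjusted_rand_score

        seqs, labels = _two_bundles(rng)
        model = cl.ts_kmeans(seqs, K=2, seed=1, n_init=2)
        assert adjusted_rand_score(labels, model.assignments) == 1.0

    def test_objective_monotone_nonincreasing(self, rng):
        seqs, _ = _two_bundles(rng)
        model = cl.ts_kmeans(seqs, K=3, seed=2, n_init=2)
        hist = model.objective_history
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_seeded_determinism(self, rng):
        seqs, _ = _two_bundles(rng)
        a = cl.ts_kmeans(seqs, K=2, seed=7, n_init=2)
        b = cl.ts_kmeans(seqs, K=2, seed=7, n_init=2)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.objective == b.objective

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.ts_kmeans([rng.normal(size=(3, 2))] * 4, K=5)


class TestValidity:
    def test_silhouette_one_for_duplicated_groups(self, rng):
        base = [rng.normal(size=(6, 2)), rng.normal(size=(9, 2)) + 30]
        seqs = [base[0]] * 5 + [base[1]] * 5
        labels = np.array([0] * 5 + [1] * 5)
        assert cl.silhouette_dtw(seqs, labels) == pytest.approx(1.0)

    def test_silhouette_near_zero_for_random_assignment(self, rng):
        seqs = [rng.normal(size=(int(rng.integers(6, 10)), 2))
                for _ in range(200)]
        labels = rng.integers(0, 4, size=200)
        assert abs(cl.silhouette_dtw(seqs, labels)) < 0.1

    def test_silhouette_precomputed_matches_on_the_fly(self, rng):
        seqs, labels = _two_bundles(rng, n_per=6)
        D = cl.pairwise_dtw(seqs)
        assert cl.silhouette_dtw(seqs, labels, D=D) == \
            pytest.approx(cl.silhouette_dtw(seqs, labels))

    def test_silhouette_undefined_flagged(self, rng):
        seqs = [rng.normal(size=(4, 2)) for _ in range(3)]
        with pytest.warns(UserWarning):
            assert np.isnan(cl.silhouette_dtw(seqs, np.array([0, 1, 2])))

    def test_dbi_small_for_tight_separated_clusters(self, rng):
        seqs, labels = _two_bundles(rng, n_per=8)
        model = cl.ts_kmeans(seqs, K=2, seed=0, n_init=2)
        assert cl.dbi_dtw(seqs, model) < 0.2

    def test_dbi_diverges_for_coincident_centroids(self, rng):
        seqs = [rng.normal(size=(5, 2)) for _ in range(4)]
        c = np.zeros((5, 2))
        model = cl.ClusterModel(K=2, centroids=[c, c.copy()],
                                assignments=np.array([0, 0, 1, 1]),
                                objective=0.0)
        with pytest.warns(UserWarning):
            assert np.isinf(cl.dbi_dtw(seqs, model))

    def test_dbi_matches_brute_force_reimplementation(self, rng):
        seqs, _ = _two_bundles(rng, n_per=10)
        model = cl.ts_kmeans(seqs, K=2, seed=3, n_init=2)
        # independent recomputation of the definition
        sig = []
        for k in range(2):
            members = [s for s, a in zip(seqs, model.assignments) if a == k]
            sig.append(np.mean([cl.dtw(s, model.centroids[k])
                                for s in members]))
        delta = cl.dtw(model.centroids[0], model.centroids[1])
        expected = (sig[0] + sig[1]) / delta
        assert cl.dbi_dtw(seqs, model) == pytest.approx(expected, rel=1e-12)


class TestSelectK:
    def test_table_has_one_row_per_k(self, rng):
        seqs, _ = _two_bundles(rng, n_per=6)
        table = cl.select_k(seqs, k_range=range(2, 6), seed=0, n_init=1)
        assert list(table["K"]) == [2, 3, 4, 5]
        assert set(table.columns) >= {"K", "J", "SS", "DBI", "acceptable"}

    def test_planted_k_flagged_acceptable(self, rng):
        seqs, _ = _two_bundles(rng, n_per=10)
        table = cl.select_k(seqs, k_range=range(2, 5), seed=0, n_init=2)
        row = table[table["K"] == 2].iloc[0]
        assert row["SS"] > 0.25 and row["DBI"] < 1.0 and row["acceptable"]


class TestBootstrapStability:
    def test_full_fraction_single_iteration_perfect_jaccard(self, rng):
        seqs, _ = _two_bundles(rng, n_per=8)
        model = cl.ts_kmeans(seqs, K=2, seed=0, n_init=2)
        rep = cl.bootstrap_stability(seqs, K=2, full_model=model, n_iter=1,
                                     frac=1.0, seed=0, n_init=2)
        assert rep["jaccard_mean"] == pytest.approx(1.0)

    def test_high_separation_stability(self, rng):
        seqs, _ = _two_bundles(rng, n_per=10)
        rep = cl.bootstrap_stability(seqs, K=2, n_iter=10, frac=0.9, seed=1,
                                     n_init=2)
        assert rep["jaccard_mean"] >= 0.8

    def test_label_permutation_invariance(self, rng):
        seqs, _ = _two_bundles(rng, n_per=8)
        model = cl.ts_kmeans(seqs, K=2, seed=0, n_init=2)
        permuted = cl.ClusterModel(
            K=2, centroids=[model.centroids[1], model.centroids[0]],
            assignments=1 - model.assignments, objective=model.objective)
        a = cl.bootstrap_stability(seqs, 2, full_model=model, n_iter=5,
                                   seed=3, n_init=1)
        b = cl.bootstrap_stability(seqs, 2, full_model=permuted, n_iter=5,
                                   seed=3, n_init=1)
        assert a["jaccard_mean"] == pytest.approx(b["jaccard_mean"])


def test_scale_sequences_unit_variance(rng):
    seqs = [rng.normal(loc=5, scale=3, size=(int(rng.integers(4, 9)), 3))
            for _ in range(10)]
    scaled = cl.scale_sequences(seqs)
    allpts = np.vstack(scaled)
    assert np.allclose(allpts.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(allpts.std(axis=0), 1, atol=1e-12)
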