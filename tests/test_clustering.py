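import itertools

import numpy as np
import pytest

from metastate import (
    MetastateKMeans,
    correlation_distance,
    elbow_select_k,
    kmeans_pp,
    match_states,
    metastate_centers,
    two_stage_fit,
)
from metastate.clustering import _distance_matrix
from metastate.synthgen import SyntheticSpec, generate_centrality_dataset, state_templates


def _zscore_rows(X):
    return (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)


class TestCorrelationDistance:
    def test_identical_vectors(self, rng):
        u = rng.standard_normal(10)
        assert correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors(self, rng):
        u = rng.standard_normal(10)
        assert correlation_distance(u, -u + 5.0) == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_half(self):
        assert correlation_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_range_bounds(self, rng):
        for _ in range(50):
            d = correlation_distance(rng.standard_normal(8), rng.standard_normal(8))
            assert 0.0 <= d <= 2.0


def _exhaustive_best_inertia(X, k):
    """Global optimum by enumerating every assignment of samples to k
    clusters (mean centers, correlation distance)."""
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        assign = np.asarray(assign)
        if len(set(assign.tolist())) < k:
            continue
        centers = np.stack([X[assign == c].mean(axis=0) for c in range(k)])
        D = _distance_matrix(X, centers)
        inertia = D[np.arange(n), assign].sum()
        best = min(best, inertia)
    return best


class TestMetastateKMeans:
    def test_identical_samples_single_center(self, rng):
        v = rng.standard_normal(12)
        X = np.tile(v, (6, 1))
        model = kmeans_pp(X, 1, seed=0)
        np.testing.assert_allclose(model.centers[0], v)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_equals_n_perfect_fit(self, rng):
        X = _zscore_rows(rng.standard_normal((5, 10)))
        model = kmeans_pp(X, 5, seed=3)
        assert model.inertia == pytest.approx(0.0, abs=1e-10)
        assert sorted(model.labels.tolist()) == [0, 1, 2, 3, 4]

    def test_two_anticorrelated_patterns_recovered(self, rng):
        base = rng.standard_normal(20)
        X = np.stack(
            [base + 0.05 * rng.standard_normal(20) for _ in range(10)]
            + [-base + 0.05 * rng.standard_normal(20) for _ in range(10)]
        )
        model = kmeans_pp(X, 2, seed=1)
        labels = model.labels
        assert len(set(labels[:10].tolist())) == 1
        assert len(set(labels[10:].tolist())) == 1
        assert labels[0] != labels[10]

    def test_centers_are_member_means(self, rng):
        X = _zscore_rows(rng.standard_normal((40, 12)))
        model = kmeans_pp(X, 3, seed=5)
        for c in range(3):
            np.testing.assert_allclose(
                model.centers[c], X[model.labels == c].mean(axis=0), atol=1e-8
            )

    def test_seed_determinism_is_bitwise(self, rng):
        X = _zscore_rows(rng.standard_normal((50, 10)))
        a = kmeans_pp(X, 4, seed=11)
        b = kmeans_pp(X, 4, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)
        assert a.inertia == b.inertia

    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 3, 1), (8, 3, 2), (8, 2, 3)])
    def test_matches_exhaustive_global_optimum(self, n, k, seed):
        rng = np.random.default_rng(seed + 100)
        X = _zscore_rows(rng.standard_normal((n, 9)))
        model = kmeans_pp(X, k, seed=seed, n_init=10)
        assert model.inertia <= _exhaustive_best_inertia(X, k) + 1e-9

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            kmeans_pp(rng.standard_normal((3, 5)), 4)

    def test_sklearn_get_set_params(self):
        est = MetastateKMeans(n_clusters=4, random_state=7)
        params = est.get_params()
        assert params["n_clusters"] == 4
        est.set_params(n_clusters=2)
        assert est.n_clusters == 2

    def test_predict_matches_labels_after_fit(self, rng):
        X = _zscore_rows(rng.standard_normal((30, 8)))
        est = MetastateKMeans(n_clusters=3, random_state=0).fit(X)
        np.testing.assert_array_equal(est.predict(X), est.labels_)


class TestMetastateCenters:
    def test_singleton_states_equal_members(self, rng):
        X = rng.standard_normal((3, 6))
        centers = metastate_centers(X, np.array([0, 1, 2]))
        np.testing.assert_allclose(centers, X)

    def test_mean_of_two_members(self, rng):
        v = rng.standard_normal(6)
        w = rng.standard_normal(6)
        centers = metastate_centers(np.stack([v, w]), np.array([0, 0]))
        np.testing.assert_allclose(centers[0], (v + w) / 2)

    def test_empty_state_rejected(self, rng):
        with pytest.raises(ValueError, match="no member"):
            metastate_centers(rng.standard_normal((3, 5)), np.array([0, 0, 2]))

    def test_planted_patterns_recovered_within_noise(self):
        spec = SyntheticSpec(n_subjects=1, n_states=3, n_regions=30,
                             windows_per_session=600, snr=5.0, seed=9)
        labels, series = generate_centrality_dataset(spec)
        centers = metastate_centers(series[0][0], labels[0][0])
        templates = state_templates(spec)
        for c in range(3):
            n_members = (labels[0][0] == c).sum()
            # template entries have unit SD; noise SD is 1/snr
            tol = 4.0 / (spec.snr * np.sqrt(n_members))
            assert np.abs(centers[c] - templates[c]).max() < tol + 0.05


class TestElbow:
    def test_recovers_five_planted_states(self):
        # enough subjects x windows that every planted state is well
        # represented in the pooled samples
        spec = SyntheticSpec(n_subjects=8, n_states=5, n_regions=40,
                             windows_per_session=120, snr=5.0, seed=21)
        _, series = generate_centrality_dataset(spec)
        pooled = np.vstack([s[0] for s in series])
        k, validity = elbow_select_k(pooled, (2, 10), seed=13)
        assert k == 5
        assert validity["k"] == list(range(2, 11))
        assert len(validity["inertia"]) == 9

    def test_single_blob_has_low_silhouette(self, rng):
        X = _zscore_rows(rng.standard_normal((150, 20)))
        k, validity = elbow_select_k(X, (2, 6), seed=3)
        sil = np.asarray(validity["silhouette"])
        assert np.nanmax(sil) < 0.3

    def test_duplicating_samples_keeps_k(self):
        spec = SyntheticSpec(n_subjects=2, n_states=3, n_regions=30,
                             windows_per_session=80, snr=5.0, seed=8)
        _, series = generate_centrality_dataset(spec)
        X = np.vstack([s[0] for s in series])
        k1, _ = elbow_select_k(X, (2, 7), seed=5)
        k2, _ = elbow_select_k(np.vstack([X, X]), (2, 7), seed=5)
        assert k1 == k2 == 3

    def test_narrow_range_rejected(self, rng):
        with pytest.raises(ValueError, match="3 values"):
            elbow_select_k(rng.standard_normal((20, 5)), (4, 5), seed=0)


class TestMatchStates:
    def test_identity(self, rng):
        C = _zscore_rows(rng.standard_normal((4, 10)))
        m = match_states(C, C)
        np.testing.assert_array_equal(m.permutation, np.arange(4))
        np.testing.assert_allclose(m.matched_distances, 0.0, atol=1e-12)

    def test_recovers_known_shuffle_vs_exhaustive(self, rng):
        import itertools as it

        C = _zscore_rows(rng.standard_normal((5, 12)))
        perm = rng.permutation(5)
        B = C[perm]  # B[i] = C[perm[i]]
        m = match_states(C, B)
        np.testing.assert_array_equal(B[m.permutation], C)
        # optimality against every bijection
        D = 1 - np.corrcoef(C, B)[:5, 5:]
        best = min(sum(D[i, p[i]] for i in range(5)) for p in it.permutations(range(5)))
        assert m.total_distance == pytest.approx(best, abs=1e-10)

    def test_single_state(self, rng):
        m = match_states(rng.standard_normal((1, 8)), rng.standard_normal((1, 8)))
        assert m.permutation.tolist() == [0]

    def test_unequal_k_rejected(self, rng):
        with pytest.raises(ValueError, match="unequal"):
            match_states(rng.standard_normal((3, 5)), rng.standard_normal((4, 5)))

    def test_total_distance_no_worse_than_identity(self, rng):
        A = _zscore_rows(rng.standard_normal((6, 15)))
        B = _zscore_rows(rng.standard_normal((6, 15)))
        m = match_states(A, B)
        identity_total = sum(correlation_distance(A[i], B[i]) for i in range(6))
        assert m.total_distance <= identity_total + 1e-12


class TestTwoStage:
    def test_single_subject_equals_pooled(self):
        spec = SyntheticSpec(n_subjects=1, n_states=3, n_regions=20,
                             windows_per_session=90, snr=5.0, seed=2)
        _, series = generate_centrality_dataset(spec)
        X = series[0][0]
        res = two_stage_fit([X], 3, seed=4)
        group_pred = np.asarray(
            _distance_matrix(X, res.group_model.centers).argmin(axis=1)
        )
        agreement = (res.subject_labels[0] == group_pred).mean()
        assert agreement > 0.95

    def test_samples_at_group_centers_do_not_move(self, rng):
        X = _zscore_rows(rng.standard_normal((60, 12)))
        res = two_stage_fit([X], 3, seed=1)
        centers = res.group_model.centers
        res2 = two_stage_fit([X, centers], 3, seed=1)
        labels = res2.subject_labels[1]
        m = match_states(centers, res2.group_model.centers)
        np.testing.assert_array_equal(labels, m.permutation[np.arange(3)])

    def test_subject_smaller_than_k_gets_nearest_center(self, rng):
        spec = SyntheticSpec(n_subjects=2, n_states=3, n_regions=20,
                             windows_per_session=50, snr=5.0, seed=6)
        _, series = generate_centrality_dataset(spec)
        tiny = series[0][0][:2]
        res = two_stage_fit([series[0][0], series[1][0], tiny], 3, seed=0)
        assert res.subject_models[2] is None
        expected = _distance_matrix(tiny, res.group_model.centers).argmin(axis=1)
        np.testing.assert_array_equal(res.subject_labels[2], expected)

    def test_planted_label_recovery_above_95(self):
        spec = SyntheticSpec(n_subjects=5, n_states=4, n_regions=40,
                             windows_per_session=80, snr=5.0, seed=31)
        labels, series = generate_centrality_dataset(spec)
        res = two_stage_fit([s[0] for s in series], 4, seed=17)
        templates = state_templates(spec)
        m = match_states(res.group_model.centers, templates)
        hits = total = 0
        for subj_lab, (true_lab, _) in zip(res.subject_labels, labels):
            hits += (m.permutation[subj_lab] == true_lab).sum()
            total += true_lab.size
        assert hits / total > 0.95

    def test_region_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="region dimension"):
            two_stage_fit([rng.standard_normal((10, 5)),
                           rng.standard_normal((10, 6))], 2)
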