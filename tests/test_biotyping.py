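"""PCA reduction, correlation-distance Ward clustering, cluster-number
selection and cross-method agreement."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score, cohen_kappa_score

from pdbiotype.biotyping import (
    _align_labels,
    calinski_harabasz,
    correlation_distance,
    discover_biotypes,
    kappa_agreement,
    kmeans_cluster,
    pca_reduce,
    select_k,
    ward_cluster,
)


def naive_ward_merges(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Brute-force agglomerator recomputing Lance-Williams Ward costs from
    the current dissimilarity matrix at every step."""
    n = D.shape[0]
    sizes = {i: 1 for i in range(n)}
    dd = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    merges, nxt = [], n
    for _ in range(n - 1):
        h, i, j = min(
            (dd[tuple(sorted((a, b)))], a, b)
            for ai, a in enumerate(active)
            for b in active[ai + 1 :]
        )
        merges.append((i, j, h))
        for k in active:
            if k in (i, j):
                continue
            ni, nj, nk = sizes[i], sizes[j], sizes[k]
            dik = dd[tuple(sorted((i, k)))]
            djk = dd[tuple(sorted((j, k)))]
            d2 = ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2) / (ni + nj + nk)
            dd[tuple(sorted((nxt, k)))] = np.sqrt(d2)
        sizes[nxt] = sizes[i] + sizes[j]
        active = [x for x in active if x not in (i, j)] + [nxt]
        nxt += 1
    return merges


class TestPCAReduce:
    def test_two_variance_directions_need_two_components(self, rng):
        # scores along two orthogonal axes carrying 80% / 20% of variance
        n = 400
        X = np.zeros((n, 6))
        X[:, 0] = rng.standard_normal(n) * 2.0
        X[:, 1] = rng.standard_normal(n) * 1.0
        comps = pca_reduce(X, var_target=0.90)
        assert comps.n_components == 2

    def test_isotropic_gaussian_needs_about_ninety_percent_of_dims(self):
        hits = []
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((4000, 10))
            hits.append(pca_reduce(X, var_target=0.90).n_components)
        assert np.median(hits) == 9

    def test_scores_preserve_total_variance_and_are_uncorrelated(self, rng):
        X = rng.standard_normal((60, 8))
        comps = pca_reduce(X, var_target=1.0)
        centred = X - X.mean(axis=0)
        assert np.isclose(comps.scores.var(axis=0).sum(), centred.var(axis=0).sum(), atol=1e-8)
        C = np.cov(comps.scores.T)
        assert np.max(np.abs(C - np.diag(np.diag(C)))) < 1e-8

    def test_ratios_non_increasing(self, rng):
        comps = pca_reduce(rng.standard_normal((50, 12)), var_target=0.9)
        assert np.all(np.diff(comps.explained_variance_ratio) <= 1e-12)

    def test_bad_target_rejected(self, rng):
        with pytest.raises(ValueError, match="var_target"):
            pca_reduce(rng.standard_normal((10, 3)), var_target=1.5)


class TestCorrelationDistance:
    def test_self_zero_negation_two(self, rng):
        row = rng.standard_normal(10)
        D = correlation_distance(np.vstack([row, row, -row]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_elementwise_pearson_oracle(self, rng):
        S = rng.standard_normal((5, 8))
        D = correlation_distance(S)
        for i in range(5):
            for j in range(5):
                expected = 1.0 - np.corrcoef(S[i], S[j])[0, 1]
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_identified(self, rng):
        S = rng.standard_normal((4, 6))
        S[2] = 3.0
        with pytest.raises(ValueError, match="row 2"):
            correlation_distance(S)


class TestWardCluster:
    def test_recovers_planted_separation(self, rng):
        S = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(8, 1, (30, 5))])
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(S))
        labels, _ = ward_cluster(D, 2)
        truth = np.repeat([1, 2], [20, 30])
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        D = correlation_distance(rng.standard_normal((6, 10)))
        labels, _ = ward_cluster(D, 6)
        assert len(set(labels)) == 6

    def test_merge_sequence_matches_brute_force_oracle(self):
        D = np.array(
            [[0, 2, 6, 10], [2, 0, 5, 9], [6, 5, 0, 4], [10, 9, 4, 0]], dtype=float
        )
        _, Z = ward_cluster(D, 2)
        oracle = naive_ward_merges(D)
        for row, (i, j, h) in zip(Z, oracle):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(h, abs=1e-10)

    def test_merge_heights_non_decreasing(self, rng):
        D = correlation_distance(rng.standard_normal((25, 12)))
        _, Z = ward_cluster(D, 2)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_invalid_matrix_rejected(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(rng.standard_normal((5, 5)), 2)

    def test_row_permutation_permutes_labels(self, rng):
        S = np.vstack([rng.normal(0, 1, (15, 6)), rng.normal(5, 1, (15, 6))])
        D = correlation_distance(S)
        labels, _ = ward_cluster(D, 2)
        perm = rng.permutation(30)
        labels_p, _ = ward_cluster(D[np.ix_(perm, perm)], 2)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0


class TestCalinskiHarabasz:
    def test_hand_value_two_hundred(self):
        S = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 1, 2, 2])
        assert calinski_harabasz(S, labels) == pytest.approx(200.0)

    def test_matches_sklearn(self, rng):
        S = rng.standard_normal((40, 4))
        labels = rng.integers(1, 4, 40)
        assert calinski_harabasz(S, labels) == pytest.approx(
            calinski_harabasz_score(S, labels), rel=1e-10
        )

    def test_invariant_to_label_permutation(self, rng):
        S = rng.standard_normal((30, 3))
        labels = rng.integers(1, 4, 30)
        swapped = np.select([labels == 1, labels == 2, labels == 3], [3, 1, 2])
        assert calinski_harabasz(S, labels) == pytest.approx(calinski_harabasz(S, swapped))

    def test_degenerate_clustering_rejected(self):
        S = np.array([[0.0], [0.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            calinski_harabasz(S, np.array([1, 1, 2, 2]))

    def test_select_k_finds_planted_two(self, rng):
        S = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(6, 1, (40, 4))])
        from scipy.spatial.distance import pdist, squareform

        k_star, ch, _ = select_k(S, range(2, 8), D=squareform(pdist(S)))
        assert k_star == 2
        assert set(ch) == set(range(2, 8))


class TestKMeans:
    def test_k_one_single_label(self, rng):
        labels = kmeans_cluster(rng.standard_normal((10, 3)), 1, seed=0)
        assert set(labels) == {1}

    def test_separated_blobs_recovered(self, rng):
        S = np.vstack([rng.normal(0, 0.5, (20, 3)), rng.normal(5, 0.5, (25, 3))])
        labels = kmeans_cluster(S, 2, seed=0)
        assert adjusted_rand_score(np.repeat([1, 2], [20, 25]), labels) == 1.0

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.standard_normal((4, 2)), 5, seed=0)


class TestKappa:
    def test_identical_labelings(self):
        labels = np.array([1, 2, 1, 2, 2])
        assert kappa_agreement(labels, labels) == pytest.approx(1.0)

    def test_hand_value_point_six(self):
        a = np.repeat([1, 1, 2, 2], [40, 10, 10, 40])
        b = np.repeat([1, 2, 1, 2], [40, 10, 10, 40])
        assert kappa_agreement(a, b) == pytest.approx(0.6)

    def test_constant_labeling_gives_zero(self):
        a = np.array([1, 1, 2, 2])
        assert kappa_agreement(a, np.array([1, 1, 1, 1])) == pytest.approx(0.0)

    def test_alignment_then_sklearn_cross_check(self, rng):
        a = rng.integers(1, 4, 60)
        b = rng.integers(1, 4, 60)
        aligned = _align_labels(a, b)
        assert kappa_agreement(a, b) == pytest.approx(cohen_kappa_score(a, aligned), abs=1e-12)

    def test_swapped_labels_still_perfect(self):
        a = np.array([1, 1, 2, 2])
        assert kappa_agreement(a, np.array([2, 2, 1, 1])) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            kappa_agreement(np.array([1, 2]), np.array([1, 2, 1]))


def test_discover_biotypes_orients_biotype1_to_atrophy(rng):
    # biotype 1 must be the cluster with the lower mean feature value;
    # the planted pattern varies across features so that subject-row
    # correlations carry it (a uniform shift would be centred away)
    pattern = rng.uniform(0.5, 1.5, 40)
    X = np.vstack(
        [
            -pattern + rng.normal(0, 0.7, (25, 40)),
            pattern + rng.normal(0, 0.7, (35, 40)),
        ]
    )
    comps, assignment = discover_biotypes(X, seed=0)
    assert assignment.k == 2
    m1 = X[assignment.labels == 1].mean()
    m2 = X[assignment.labels == 2].mean()
    assert m1 < m2
    assert assignment.kappa_kmeans is not None
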