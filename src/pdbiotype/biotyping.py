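"""Patient biotyping: PCA reduction and hierarchical clustering.

The selected (residualized) voxel features are reduced to the smallest
principal-component space explaining at least 90% of the variance.  A
correlation-distance matrix between participants' component-score rows is
clustered with Ward minimum-variance agglomeration (Lance-Williams update
applied to the supplied dissimilarities — formally a heuristic for
non-Euclidean input, used deliberately as the field does), the cluster
number is chosen by the Calinski-Harabasz criterion over the Ward cuts,
and cross-method stability is quantified by Cohen's kappa against a
k-means solution on the same component scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ComponentScores",
    "BiotypeAssignment",
    "pca_reduce",
    "correlation_distance",
    "ward_cluster",
    "calinski_harabasz",
    "select_k",
    "kmeans_cluster",
    "kappa_agreement",
    "discover_biotypes",
]


@dataclass
class ComponentScores:
    """Principal-component scores retained to a cumulative variance target."""

    scores: np.ndarray  # subjects x n_components
    explained_variance_ratio: np.ndarray  # all components, non-increasing
    var_target: float
    n_components: int


@dataclass
class BiotypeAssignment:
    """Cluster solution with its selection diagnostics."""

    labels: np.ndarray  # in {1..k}
    linkage: np.ndarray  # scipy linkage matrix
    k: int
    ch_by_k: dict[int, float]
    kappa_kmeans: float | None = None
    kmeans_labels: np.ndarray | None = None


def pca_reduce(X: np.ndarray, var_target: float = 0.90) -> ComponentScores:
    """Project subjects onto the leading principal components.

    Columns are centred (not variance-standardized); ``n_components`` is
    the smallest k whose cumulative explained-variance ratio reaches
    ``var_target``.
    """
    if not 0 < var_target <= 1:
        raise ValueError(f"var_target must lie in (0, 1], got {var_target}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a subjects x features matrix with >= 2 subjects")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    n_comp = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    # at least two components: downstream subject-by-subject correlation
    # distance is undefined on single-column score rows
    n_comp = min(max(n_comp, 2), scores.shape[1])
    return ComponentScores(
        scores=scores[:, :n_comp],
        explained_variance_ratio=ratio,
        var_target=float(var_target),
        n_components=n_comp,
    )


def correlation_distance(S: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson(row_i, row_j): symmetric, zero diagonal, in [0, 2]."""
    S = np.asarray(S, dtype=float)
    sd = S.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"subject row {bad} is constant; correlation distance undefined")
    Z = (S - S.mean(axis=1, keepdims=True)) / (sd * np.sqrt(S.shape[1]))[:, None]
    D = 1.0 - Z @ Z.T
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return D


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, with a zero diagonal")
    return D


def ward_cluster(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward agglomeration of a precomputed dissimilarity matrix.

    Returns (labels in {1..k}, scipy linkage matrix).  Labels come from
    cutting the tree at k clusters.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    Z = linkage(squareform(D, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels.astype(int), Z


def calinski_harabasz(S: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion [B/(k-1)] / [W/(n-k)] in component space."""
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = S.shape[0], uniq.size
    if k < 2:
        raise ValueError("need >= 2 non-empty clusters")
    mu = S.mean(axis=0)
    B = W = 0.0
    for c in uniq:
        Sc = S[labels == c]
        mc = Sc.mean(axis=0)
        B += Sc.shape[0] * float(((mc - mu) ** 2).sum())
        W += float(((Sc - mc) ** 2).sum())
    if W == 0:
        raise ValueError("degenerate clustering: zero within-cluster dispersion")
    return (B / (k - 1)) / (W / (n - k))


def select_k(
    S: np.ndarray,
    k_range: range = range(2, 11),
    D: np.ndarray | None = None,
) -> tuple[int, dict[int, float], np.ndarray]:
    """Choose the cluster number maximizing Calinski-Harabasz over Ward cuts.

    Clustering runs on the correlation distances of ``S`` (or a supplied
    ``D``); the criterion itself is evaluated on the component scores with
    Euclidean geometry.  Returns (k*, CH per candidate k, linkage matrix).
    """
    if D is None:
        D = correlation_distance(S)
    D = _check_distance_matrix(D)
    Z = linkage(squareform(D, checks=False), method="ward")
    ch: dict[int, float] = {}
    for k in k_range:
        if k >= D.shape[0]:
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        ch[k] = calinski_harabasz(S, labels)
    if not ch:
        raise ValueError("empty candidate range")
    k_star = max(ch, key=lambda k: (ch[k], -k))
    return k_star, ch, Z


def kmeans_cluster(S: np.ndarray, k: int, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Best-of-n_init Lloyd k-means on the component scores; labels in {1..k}."""
    S = np.asarray(S, dtype=float)
    if k > S.shape[0]:
        raise ValueError(f"k={k} exceeds the number of subjects {S.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(S).astype(int) + 1


def _align_labels(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Permute `other`'s label values to maximize raw agreement with `reference`."""
    ref_vals = np.unique(reference)
    oth_vals = np.unique(other)
    if oth_vals.size > 6:
        raise ValueError("exhaustive label alignment supported for <= 6 clusters")
    best, best_hits = other, -1
    for perm in itertools.permutations(ref_vals, oth_vals.size):
        mapping = dict(zip(oth_vals, perm))
        mapped = np.vectorize(mapping.get)(other)
        hits = int((mapped == reference).sum())
        if hits > best_hits:
            best, best_hits = mapped, hits
    return best


def kappa_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Cohen's kappa after exhaustive-permutation label alignment.

    Cluster labels are arbitrary, so ``labels_b`` is first re-mapped by the
    permutation maximizing raw agreement with ``labels_a``; kappa is then
    (p_o - p_e) / (1 - p_e) with chance agreement from the marginals.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    b = _align_labels(a, b)
    vals = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float((a == b).sum()) / n
    p_e = sum(float((a == v).sum()) * float((b == v).sum()) for v in vals) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def discover_biotypes(
    X: np.ndarray,
    var_target: float = 0.90,
    k_range: range = range(2, 11),
    k: int | None = None,
    seed: int = 0,
    kmeans_n_init: int = 50,
) -> tuple[ComponentScores, BiotypeAssignment]:
    """PCA -> correlation-distance Ward -> CH selection -> kappa vs k-means.

    ``k=None`` selects the cluster number by the Calinski-Harabasz
    criterion; an explicit ``k`` forces the cut.
    """
    comps = pca_reduce(X, var_target=var_target)
    D = correlation_distance(comps.scores)
    k_star, ch, Z = select_k(comps.scores, k_range=k_range, D=D)
    if k is not None:
        k_star = k
    labels = fcluster(Z, t=k_star, criterion="maxclust").astype(int)
    km_labels = kmeans_cluster(comps.scores, k_star, seed=seed, n_init=kmeans_n_init)
    kappa = kappa_agreement(labels, km_labels)
    # convention: for k=2, biotype 1 = cluster with the lower mean feature
    # value, i.e. the locally-smaller-volume (atrophy) group
    if k_star == 2:
        Xm = np.asarray(X, dtype=float).mean(axis=1)
        m1 = Xm[labels == 1].mean()
        m2 = Xm[labels == 2].mean()
        if m1 > m2:
            labels = np.where(labels == 1, 2, 1)
            km_labels = _align_labels(labels, km_labels)
    assignment = BiotypeAssignment(
        labels=labels, linkage=Z, k=k_star, ch_by_k=ch, kappa_kmeans=kappa, kmeans_labels=km_labels
    )
    return comps, assignment
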