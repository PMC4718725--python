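"""Co-expression clustering: Partitioning Around Medoids (PAM) under
correlation distance, with the cluster-count rule that k is the largest
number of clusters for which "non-representative" small clusters (fewer
than 1% of genes) hold no more than 5% of all genes.

PAM is the classical BUILD + SWAP algorithm on a precomputed distance
matrix; assignment and swap ties are broken by lowest index, so the result
is deterministic for a given distance matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - r (Pearson) distance between row profiles.

    Entries lie in [0, 2]: 0 for identical shape, 2 for an exact sign flip.
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("profiles need at least 2 columns")
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance profile(s): "
                         f"rows {np.where(sd == 0)[0][:5].tolist()}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    nearest = D[first].copy()
    while len(medoids) < k:
        # gain of adding candidate c = total reduction in nearest distances
        gain = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, D[c])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], tol: float = 1e-12
              ) -> list[int]:
    n = len(D)
    medoids = list(medoids)
    while True:
        M = np.array(medoids)
        dm = D[M]                               # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        near_idx = order[0]                     # index into M
        d1 = dm[near_idx, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if len(M) > 1 else np.full(n, np.inf)

        nonmed = np.setdiff1d(np.arange(n), M, assume_unique=False)
        Dh = D[nonmed]                          # h x n
        G = np.minimum(Dh - d1[None, :], 0.0)   # gain from h regardless of m
        base = G.sum(axis=1)                    # per-h
        # per (h, m): points whose nearest is m get min(Dh, d2) - d1 instead
        T = np.tile(base[:, None], (1, len(M)))
        repl = np.minimum(Dh, d2[None, :]) - d1[None, :]
        extra = repl - G
        for mi in range(len(M)):
            mask = near_idx == mi
            if mask.any():
                T[:, mi] += extra[:, mask].sum(axis=1)
        best = np.unravel_index(np.argmin(T), T.shape)
        if T[best] >= -tol:
            return medoids
        h, mi = int(nonmed[best[0]]), int(best[1])
        medoids[mi] = h


def pam(distances: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PAM on a precomputed distance matrix.

    Returns (labels, medoid indices); labels index into the medoid array.
    Deterministic: BUILD initialization, then best-improvement swaps with
    lowest-index tie-breaks.
    """
    D = np.asarray(distances, dtype=float)
    n = len(D)
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    medoids = _pam_swap(D, _pam_build(D, k)) if k < n else list(range(n))
    M = np.array(sorted(medoids))
    labels = np.argmin(D[M], axis=0)
    return labels, M


def small_cluster_mass(labels: np.ndarray, min_frac: float = 0.01) -> float:
    """Fraction of genes in clusters holding fewer than ``min_frac`` of all
    genes."""
    n = len(labels)
    _, sizes = np.unique(labels, return_counts=True)
    return float(sizes[sizes < min_frac * n].sum()) / n


def select_k(distances: np.ndarray, k_max: int = 80,
             min_frac: float = 0.01, max_mass: float = 0.05
             ) -> tuple[int, bool]:
    """Largest k in [2, k_max] whose PAM solution keeps the mass of small
    clusters (< ``min_frac`` of genes) at or below ``max_mass``.

    Scans downward from ``k_max`` and returns the first admissible k.
    Returns (k, fallback flag); the flag is set when no k satisfies the
    rule and k=2 is returned.
    """
    n = len(distances)
    if k_max >= n:
        k_max = n - 1
    for k in range(k_max, 1, -1):
        labels, _ = pam(distances, k)
        if small_cluster_mass(labels, min_frac) <= max_mass:
            return k, False
    return 2, True


def cluster_means(profiles: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Mean scaled profile per cluster (clusters x columns)."""
    out = {}
    for c in np.unique(labels):
        out[c] = profiles.iloc[np.where(labels == c)[0]].mean(axis=0)
    return pd.DataFrame(out).T.sort_index()


class PAMClusterer(BaseEstimator, ClusterMixin):
    """Correlation-distance PAM with the 5% / 1% cluster-count rule.

    Parameters
    ----------
    n_clusters : int or "auto"
        Fixed k, or "auto" to pick the largest admissible k (descending
        scan bounded by ``k_max``).
    k_max : int
        Upper bound of the k scan in "auto" mode.
    metric : {"correlation", "precomputed"}
        Distance between gene profiles; "correlation" is 1 - Pearson r.
    min_cluster_frac, max_small_mass : float
        The representativeness rule: clusters below ``min_cluster_frac`` of
        all genes are "small"; their total mass may not exceed
        ``max_small_mass``.

    Attributes
    ----------
    labels_ : ndarray
        Cluster label per gene, 1..k, ordered so that cluster 1 is the
        largest.
    medoid_indices_ : ndarray
        Row index of each cluster's medoid, aligned with cluster order.
    cluster_sizes_ : ndarray, nonincreasing.
    n_clusters_ : int
    small_rule_failed_ : bool
        True when "auto" found no admissible k and fell back to k=2.
    """

    def __init__(self, n_clusters="auto", k_max: int = 80,
                 metric: str = "correlation",
                 min_cluster_frac: float = 0.01,
                 max_small_mass: float = 0.05):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.metric = metric
        self.min_cluster_frac = min_cluster_frac
        self.max_small_mass = max_small_mass

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.metric == "correlation":
            D = correlation_distance(X)
        elif self.metric == "precomputed":
            D = X
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.small_rule_failed_ = False
        if self.n_clusters == "auto":
            k, self.small_rule_failed_ = select_k(
                D, k_max=self.k_max, min_frac=self.min_cluster_frac,
                max_mass=self.max_small_mass)
        else:
            k = int(self.n_clusters)
        raw_labels, medoids = pam(D, k)
        # order clusters by decreasing size; ties by lowest medoid index
        _, sizes = np.unique(raw_labels, return_counts=True)
        order = sorted(range(k), key=lambda c: (-sizes[c], medoids[c]))
        relabel = {old: new + 1 for new, old in enumerate(order)}
        self.labels_ = np.array([relabel[c] for c in raw_labels])
        self.medoid_indices_ = medoids[np.array(order)]
        self.cluster_sizes_ = sizes[np.array(order)]
        self.n_clusters_ = k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def means(self, profiles: pd.DataFrame) -> pd.DataFrame:
        """Cluster-mean profiles (cluster id x columns) of the fitted
        partition."""
        check_is_fitted(self, "labels_")
        return cluster_means(profiles, self.labels_)
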