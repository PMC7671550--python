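"""Cluster validity: silhouette, fuzzy silhouette, k selection, ARI.

The silhouette of unit i compares its average dissimilarity a(i) to the
other members of its own cluster with the smallest average dissimilarity
b(i) to another cluster: s(i) = (b - a) / max(a, b) in [-1, 1].  The
fuzzy silhouette FS(k) weights each s(i) by (u_ig - u_ig')^gamma, the
gap between the unit's two largest membership degrees, so units close to
a prototype count more than units in overlap zones.  The number of
clusters is chosen by maximizing FS(k), while also reporting every k
whose FS falls within a tolerance of the maximum (picking strictly the
argmax can be too drastic; near-optimal solutions may be more
interpretable).

Distances default to squared Euclidean on coefficient vectors, matching
the clustering objective; plain Euclidean is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .clustering import FuzzyKMedoids

__all__ = [
    "ValidityReport",
    "KSelectionResult",
    "silhouette_values",
    "silhouette_index",
    "fuzzy_silhouette",
    "select_k",
    "adjusted_rand_index",
    "harden",
]


def harden(U) -> np.ndarray:
    """Hard labels by maximum membership; ties go to the lowest cluster index."""
    return np.argmax(np.asarray(U, dtype=float), axis=1)


def _distance_matrix(C, metric: str) -> np.ndarray:
    if metric not in ("sqeuclidean", "euclidean"):
        raise ValueError("metric must be 'sqeuclidean' or 'euclidean'")
    return cdist(C, C, metric=metric)


def silhouette_values(C, labels, metric: str = "sqeuclidean") -> np.ndarray:
    """Per-unit silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i) is the mean distance to the other members of i's cluster; b(i)
    the smallest mean distance to the members of another cluster.  Units
    in singleton clusters get s(i) = 0 by convention.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != C.shape[0]:
        raise ValueError("labels length does not match the number of units")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = _distance_matrix(C, metric)
    n = len(labels)
    s = np.zeros(n)
    # mean distance of every unit to every cluster
    means = np.column_stack(
        [D[:, labels == g].sum(axis=1) for g in clusters]
    )
    sizes = np.array([(labels == g).sum() for g in clusters])
    for i in range(n):
        gi = int(np.flatnonzero(clusters == labels[i])[0])
        if sizes[gi] == 1:
            s[i] = 0.0
            continue
        a = means[i, gi] / (sizes[gi] - 1)  # excludes self (D[i, i] = 0)
        others = np.flatnonzero(clusters != labels[i])
        b = np.min(means[i, others] / sizes[others])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_index(C, labels, metric: str = "sqeuclidean") -> float:
    """Average silhouette S(k)."""
    return float(np.mean(silhouette_values(C, labels, metric)))


def fuzzy_silhouette(C, U, gamma: float = 1.0, metric: str = "sqeuclidean") -> float:
    """Fuzzy silhouette FS(k): membership-gap-weighted mean of s(i).

    Weights are (u_ig - u_ig')^gamma with u_ig >= u_ig' the two largest
    memberships of unit i; gamma = 0 recovers the plain average S(k), as
    does any hard (one-hot) membership matrix.
    """
    U = np.asarray(U, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    labels = harden(U)
    s = silhouette_values(C, labels, metric)
    top2 = np.sort(U, axis=1)[:, -2:]
    gap = top2[:, 1] - top2[:, 0]
    weights = np.ones_like(gap) if gamma == 0 else gap**gamma
    total = weights.sum()
    if total <= 0:
        raise ValueError("all membership rows are uniform: zero total weight")
    return float(np.sum(weights * s) / total)


@dataclass
class ValidityReport:
    """Per-unit silhouettes and summary indices for one partition."""

    s_values: np.ndarray
    S: float
    FS: float
    gamma: float
    k: int


@dataclass
class KSelectionResult:
    """FS(k) over a k range with the recommended and near-optimal k."""

    table: pd.DataFrame  # columns k, FS, S, objective
    best_k: int
    near_best: list
    partitions: dict


def select_k(
    C,
    k_range,
    fuzziness: float = 1.5,
    gamma: float = 1.0,
    metric: str = "sqeuclidean",
    tolerance: float = 0.05,
    n_starts: int = 30,
    tol: float = 1e-6,
    max_iter: int = 1000,
    random_state=None,
) -> KSelectionResult:
    """Choose the number of clusters by the fuzzy silhouette.

    Runs fuzzy k-medoids for each k in ``k_range``, computes FS(k), and
    recommends the argmax together with every k whose FS lies within
    ``tolerance`` of the maximum.
    """
    C = np.asarray(C, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] >= C.shape[0]:
        raise ValueError("k range must lie within [2, n-1]")
    rows, partitions = [], {}
    for k in ks:
        est = FuzzyKMedoids(
            n_clusters=k, fuzziness=fuzziness, tol=tol, max_iter=max_iter,
            n_starts=n_starts, random_state=random_state,
        ).fit(C)
        fs = fuzzy_silhouette(C, est.membership_, gamma=gamma, metric=metric)
        S = silhouette_index(C, est.labels_, metric=metric)
        rows.append((k, fs, S, est.objective_))
        partitions[k] = est
    table = pd.DataFrame(rows, columns=["k", "FS", "S", "objective"])
    best_k = int(table.loc[table["FS"].idxmax(), "k"])
    fs_max = table["FS"].max()
    near = table.loc[table["FS"] >= fs_max - tolerance, "k"].astype(int).tolist()
    return KSelectionResult(table=table, best_k=best_k, near_best=near, partitions=partitions)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two hard partitions (ARI <= 1)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
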