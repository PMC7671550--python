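"""Fuzzy k-medoids and fuzzy k-means clustering on coefficient vectors.

The fuzzy k-medoids problem minimizes

    J(U, H) = sum_i sum_l u_il^f d^2(c_i, h_l)

over membership matrices U (rows on the simplex) and prototype rows H
constrained to be observed units (medoids), with fuzziness exponent f > 1
and d^2 the squared Euclidean distance between coefficient vectors.  The
alternating algorithm updates medoids (per-cluster weighted-cost argmin
over all units) and memberships

    u_il = d^2(c_i, h_l)^{-1/(f-1)} / sum_l' d^2(c_i, h_l')^{-1/(f-1)},

with units coinciding with a medoid assigned crisply, until successive
membership matrices differ by at most ``tol`` in Frobenius norm.  Each
step cannot increase the objective; multiple random starts guard against
local minima.  Dropping the medoid constraint gives fuzzy k-means, whose
prototypes are the membership-weighted means of the units.

The same estimators accept raw observed series as rows, so the raw-data
variants (no smoothing) need no separate code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

__all__ = [
    "FuzzyPartition",
    "FuzzyKMedoids",
    "FuzzyKMeans",
    "fkmed",
    "fkm",
    "update_medoids",
    "update_memberships",
    "objective",
    "global_oracle_fkmed",
]


@dataclass
class FuzzyPartition:
    """A fitted fuzzy partition.

    ``medoid_indices`` is set by the medoid-based algorithm, ``centroids``
    by the means-based one.  ``membership`` rows sum to 1.
    """

    membership: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    fuzziness: float
    medoid_indices: np.ndarray | None = None
    centroids: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment by maximum membership (ties to the lowest cluster)."""
        return np.argmax(self.membership, axis=1)


def _sq_distances(A, B=None) -> np.ndarray:
    B = A if B is None else B
    return cdist(np.atleast_2d(A), np.atleast_2d(B), metric="sqeuclidean")


def _memberships_from_distances(d2: np.ndarray, f: float) -> np.ndarray:
    """Membership update from an (n, k) matrix of squared distances."""
    n, k = d2.shape
    U = np.zeros((n, k))
    zero = d2 <= 0.0
    crisp = zero.any(axis=1)
    if crisp.any():
        # unit coincides with a prototype: full membership to (the first of) it
        first = np.argmax(zero[crisp], axis=1)
        U[np.flatnonzero(crisp), first] = 1.0
    rest = ~crisp
    if rest.any():
        w = d2[rest] ** (-1.0 / (f - 1.0))
        U[rest] = w / w.sum(axis=1, keepdims=True)
    return U


def update_memberships(C, medoid_indices, f: float) -> np.ndarray:
    """Membership degrees of every unit to the given medoids."""
    C = np.asarray(C, dtype=float)
    medoid_indices = np.asarray(medoid_indices, dtype=int)
    if len(set(medoid_indices.tolist())) != len(medoid_indices):
        raise ValueError("medoid indices must be distinct")
    return _memberships_from_distances(_sq_distances(C, C[medoid_indices]), f)


def _update_medoids_from_D(D: np.ndarray, U: np.ndarray, f: float) -> np.ndarray:
    """Medoid update given the full (n, n) squared-distance matrix.

    Per cluster the medoid is the unit minimizing the membership-weighted
    total squared distance; argmin ties break to the smallest index.  If
    two clusters pick the same unit, the one with the lower weighted cost
    keeps it and the other moves to its best not-yet-taken candidate.
    """
    costs = D @ (U**f)  # costs[i, l] = sum_i' u_i'l^f D[i, i']
    n, k = U.shape
    order = np.argsort(costs.min(axis=0), kind="stable")  # cheapest clusters first
    taken: set[int] = set()
    medoids = np.empty(k, dtype=int)
    for l in order:
        ranked = np.argsort(costs[:, l], kind="stable")
        choice = next(int(i) for i in ranked if int(i) not in taken)
        medoids[l] = choice
        taken.add(choice)
    return medoids


def update_medoids(C, U, f: float) -> np.ndarray:
    """Medoid update from coefficients and memberships (see Step 1)."""
    C = np.asarray(C, dtype=float)
    U = np.asarray(U, dtype=float)
    return _update_medoids_from_D(_sq_distances(C), U, f)


def objective(C, U, medoid_indices, f: float) -> float:
    """Weighted within-cluster dispersion sum_i sum_l u_il^f d^2(c_i, h_l)."""
    C = np.asarray(C, dtype=float)
    U = np.asarray(U, dtype=float)
    d2 = _sq_distances(C, C[np.asarray(medoid_indices, dtype=int)])
    return float(np.sum(U**f * d2))


def _random_membership_from_D(D: np.ndarray, k: int, f: float, rng) -> np.ndarray:
    """Random membership matrix seeding one start.

    Each start draws k distinct units uniformly at random and takes the
    optimal memberships to those units as prototypes.  Unlike rows drawn
    from a flat Dirichlet — which average out in the weighted medoid
    update, funnelling every start into the same basin — random-prototype
    starts explore distinct basins of the alternating algorithm.
    """
    idx = rng.choice(D.shape[0], size=k, replace=False)
    return _memberships_from_distances(D[:, idx], f)


def _check_problem(n, k, f):
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= n_clusters < n_samples, got k={k}, n={n}")
    if not f > 1:
        raise ValueError("fuzziness must exceed 1")


class FuzzyKMedoids(ClusterMixin, BaseEstimator):
    """Fuzzy k-medoids clustering with multiple random starts.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (2 <= k < n_samples).
    fuzziness : float
        Exponent f > 1; f <= 1.5 is recommended for medoid-based
        algorithms (f -> 1 hardens the partition, large f flattens
        memberships toward 1/k).
    tol : float
        Convergence threshold on the Frobenius norm of successive
        membership matrices.
    max_iter : int
        Iteration cap per start.
    n_starts : int
        Random restarts; the lowest-objective solution is kept.
    random_state : int, Generator or None
        Seeds the random membership initializations.

    Attributes
    ----------
    membership_ : (n, k) membership matrix of the best start.
    medoid_indices_ : (k,) indices of the medoid units.
    cluster_centers_ : coefficient rows of the medoids.
    labels_ : hard assignment by maximum membership.
    objective_ : best objective value.
    n_iter_, converged_ : iterations and convergence flag of the best start.
    objective_histories_ : per-start lists of the objective after each
        iteration (each list is non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        fuzziness: float = 1.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
        n_starts: int = 30,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state

    def _run(self, D, U, f):
        history = []
        medoids = None
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            medoids = _update_medoids_from_D(D, U, f)
            U_new = _memberships_from_distances(D[:, medoids], f)
            history.append(float(np.sum(U_new**f * D[:, medoids])))
            delta = np.linalg.norm(U_new - U)
            U = U_new
            if delta <= self.tol:
                converged = True
                break
        return U, medoids, history, n_iter, converged

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        k, f = self.n_clusters, self.fuzziness
        _check_problem(n, k, f)
        rng = check_random_state(self.random_state)
        D = _sq_distances(X)

        best = None
        self.objective_histories_ = []
        for _ in range(self.n_starts):
            U0 = _random_membership_from_D(D, k, f, rng)
            U, medoids, history, n_iter, converged = self._run(D, U0, f)
            self.objective_histories_.append(history)
            if best is None or history[-1] < best[0]:
                best = (history[-1], U, medoids, n_iter, converged)

        self.objective_, self.membership_, self.medoid_indices_ = best[0], best[1], best[2]
        self.n_iter_, self.converged_ = best[3], best[4]
        self.cluster_centers_ = X[self.medoid_indices_].copy()
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_membership(self, X) -> np.ndarray:
        """Membership of (new) units to the fitted medoids."""
        if not hasattr(self, "cluster_centers_"):
            raise ValueError("estimator is not fitted")
        d2 = _sq_distances(np.asarray(X, dtype=float), self.cluster_centers_)
        return _memberships_from_distances(d2, self.fuzziness)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_membership(X), axis=1)

    def to_partition(self) -> FuzzyPartition:
        return FuzzyPartition(
            membership=self.membership_,
            objective=self.objective_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            fuzziness=self.fuzziness,
            medoid_indices=self.medoid_indices_,
        )


class FuzzyKMeans(FuzzyKMedoids):
    """Fuzzy k-means: prototypes are membership-weighted means, not units.

    Same interface as :class:`FuzzyKMedoids`; ``cluster_centers_`` holds
    the fitted centroid matrix and there are no medoid indices.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        k, f = self.n_clusters, self.fuzziness
        _check_problem(n, k, f)
        rng = check_random_state(self.random_state)

        D = _sq_distances(X)
        best = None
        self.objective_histories_ = []
        for _ in range(self.n_starts):
            U = _random_membership_from_D(D, k, f, rng)
            history = []
            converged = False
            n_iter = 0
            H = None
            for n_iter in range(1, self.max_iter + 1):
                W = U**f
                H = (W.T @ X) / W.sum(axis=0)[:, None]
                d2 = _sq_distances(X, H)
                U_new = _memberships_from_distances(d2, f)
                history.append(float(np.sum(U_new**f * _sq_distances(X, H))))
                delta = np.linalg.norm(U_new - U)
                U = U_new
                if delta <= self.tol:
                    converged = True
                    break
            if best is None or history[-1] < best[0]:
                best = (history[-1], U, H, n_iter, converged)
            self.objective_histories_.append(history)

        self.objective_, self.membership_, self.cluster_centers_ = best[0], best[1], best[2]
        self.n_iter_, self.converged_ = best[3], best[4]
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def to_partition(self) -> FuzzyPartition:
        return FuzzyPartition(
            membership=self.membership_,
            objective=self.objective_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            fuzziness=self.fuzziness,
            centroids=self.cluster_centers_,
        )


def fkmed(
    C,
    k: int,
    f: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_starts: int = 30,
    seed=None,
) -> FuzzyPartition:
    """Functional fuzzy k-medoids on a coefficient matrix (thin wrapper)."""
    est = FuzzyKMedoids(
        n_clusters=k, fuzziness=f, tol=tol, max_iter=max_iter,
        n_starts=n_starts, random_state=seed,
    ).fit(C)
    return est.to_partition()


def fkm(
    C,
    k: int,
    f: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_starts: int = 30,
    seed=None,
) -> FuzzyPartition:
    """Functional fuzzy k-means on a coefficient matrix (thin wrapper)."""
    est = FuzzyKMeans(
        n_clusters=k, fuzziness=f, tol=tol, max_iter=max_iter,
        n_starts=n_starts, random_state=seed,
    ).fit(C)
    return est.to_partition()


def global_oracle_fkmed(C, k: int, f: float):
    """Global optimum by exhaustive enumeration of medoid subsets.

    Test oracle only: enumerates all k-subsets of units as medoids, pairs
    each with its optimal membership matrix, and returns
    ``(medoid_indices, U, objective)`` at the global minimum.  Restricted
    to n <= 15 units.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if n > 15:
        raise ValueError("oracle restricted to n <= 15 units")
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if not f > 1:
        raise ValueError("fuzziness must exceed 1")
    D = _sq_distances(C)
    best = None
    for subset in combinations(range(n), k):
        idx = np.array(subset)
        U = _memberships_from_distances(D[:, idx], f)
        obj = float(np.sum(U**f * D[:, idx]))
        if best is None or obj < best[2]:
            best = (idx, U, obj)
    return best
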