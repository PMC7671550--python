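"""Penalized B-spline smoothing of daily score series.

Each patient's noisy daily series y_ij is represented as a smooth function
x_i(t) = sum_p c_ip phi_p(t) in a B-spline basis with q equally spaced
interior knots and order m (degree + 1), giving s = q + m basis functions.
Coefficients are estimated by penalized least squares

    PENSSE(lambda) = ||y_i - Phi c_i||^2 + lambda * c_i' R c_i,

where R is the roughness-penalty matrix R_pp' = integral of
D^d phi_p(t) D^d phi_p'(t) dt (default d = 2, penalizing curvature).  The
smoothing parameter is chosen by generalized cross-validation,

    GCV_i = v_i * SSE_i / (v_i - df(lambda))^2,

with df(lambda) the trace of the smoothing ("hat") operator.  Because the
downstream clustering compares coefficient vectors across patients, a
single (q, m, lambda) is shared by the whole cohort: for each candidate
(q, m) the shared lambda minimizes TGCV = sum_i GCV_i over a grid
lambda = 10^g, and (q*, m*) minimizes the resulting TGCV, optionally
overridden toward a more parsimonious model whose TGCV is within a stated
tolerance of the minimum.

Numerics: the lambda profile uses a generalized-eigenvalue
reparametrization (Cholesky of Phi'Phi, then an eigendecomposition of the
penalty in that metric) so that SSE(lambda) and df(lambda) over the whole
grid cost one decomposition; eigenvalues below 1e-11 of the largest are
clamped to zero so that lambda -> infinity reproduces the least-squares
fit restricted to the penalty nullspace (a straight line for d = 2)
exactly instead of drowning in round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import linalg
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BasisSpec",
    "FunctionalFit",
    "GridSearchResult",
    "build_basis",
    "penalty_matrix",
    "fit_penalized",
    "select_lambda",
    "evaluate_curve",
    "tgcv_grid_search",
    "PenalizedBSplineSmoother",
    "DEFAULT_GRID",
]

#: Default exponent grid for lambda = 10^g.
DEFAULT_GRID = (-30.0, 20.0, 0.05)

_EIG_CLAMP = 1e-11


@dataclass(frozen=True)
class BasisSpec:
    """B-spline basis configuration.

    ``n_knots`` (q) interior knots are equally spaced strictly inside
    ``domain``; ``order`` (m) is polynomial degree + 1; the basis dimension
    is s = q + m.  ``penalty_order`` is the derivative order d of the
    roughness penalty and must be below the order.
    """

    domain: tuple
    n_knots: int
    order: int = 4
    penalty_order: int = 2

    def __post_init__(self):
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("degenerate domain")
        if self.n_knots < 0:
            raise ValueError("n_knots must be >= 0")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.penalty_order >= self.order:
            raise ValueError("penalty_order must be below the spline order")

    @property
    def size(self) -> int:
        """Basis dimension s = q + m."""
        return self.n_knots + self.order

    def interior_knots(self) -> np.ndarray:
        lo, hi = self.domain
        return lo + (hi - lo) * np.arange(1, self.n_knots + 1) / (self.n_knots + 1)

    def knot_vector(self) -> np.ndarray:
        """Full knot sequence with boundary knots repeated to the order."""
        lo, hi = self.domain
        return np.concatenate(
            [np.full(self.order, lo), self.interior_knots(), np.full(self.order, hi)]
        )


class BSplineBasis:
    """Evaluator for the B-spline system of a :class:`BasisSpec`."""

    def __init__(self, spec: BasisSpec):
        self.spec = spec
        self._knots = spec.knot_vector()
        self._degree = spec.order - 1
        # identity coefficients give the vector of basis functions
        self._spline = BSpline(self._knots, np.eye(spec.size), self._degree)

    def _check_times(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.spec.domain
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError("evaluation times outside the basis domain")
        return np.clip(t, lo, hi)

    def design_matrix(self, times) -> np.ndarray:
        """Matrix Phi with Phi[j, p] = phi_p(t_j)."""
        return self._spline(self._check_times(times))

    def derivative_matrix(self, times, d: int) -> np.ndarray:
        """Matrix of d-th derivatives of the basis functions."""
        if d == 0:
            return self.design_matrix(times)
        return self._spline.derivative(d)(self._check_times(times))


def build_basis(spec: BasisSpec) -> BSplineBasis:
    """Construct the basis evaluator for ``spec``."""
    return BSplineBasis(spec)


def penalty_matrix(spec: BasisSpec, basis: BSplineBasis | None = None) -> np.ndarray:
    """Roughness-penalty matrix R_pp' = int D^d phi_p D^d phi_p' dt.

    Computed exactly by Gauss-Legendre quadrature on each inter-knot
    interval (the integrand is a piecewise polynomial of degree
    2(m - 1 - d), so m - d nodes per interval suffice).
    """
    basis = basis or build_basis(spec)
    d = spec.penalty_order
    m = spec.order
    lo, hi = spec.domain
    breaks = np.concatenate([[lo], spec.interior_knots(), [hi]])
    npts = max(1, m - d)
    nodes, weights = leggauss(npts)
    R = np.zeros((spec.size, spec.size))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        t = 0.5 * (a + b) + half * nodes
        D = basis.derivative_matrix(t, d)
        R += half * (D * weights[:, None]).T @ D
    return 0.5 * (R + R.T)


@dataclass
class FunctionalFit:
    """Penalized least-squares fit for one unit."""

    coefficients: np.ndarray
    lam: float
    sse: float
    df: float
    gcv: float
    residuals: np.ndarray = field(default=None, repr=False)
    singular: bool = False


class _LambdaProfile:
    """Shared machinery for evaluating SSE(lambda) and df(lambda) cheaply.

    Requires Phi'Phi positive definite (s <= v with distinct times); callers
    fall back to direct per-lambda solves otherwise.
    """

    def __init__(self, Phi: np.ndarray, R: np.ndarray, Y: np.ndarray):
        self.Phi = Phi
        self.Y = Y  # (n_units, v)
        A = Phi.T @ Phi
        self.L = linalg.cholesky(A, lower=True)  # may raise LinAlgError
        K = linalg.solve_triangular(self.L, R, lower=True)
        K = linalg.solve_triangular(self.L, K.T, lower=True)
        gamma, Q = linalg.eigh(0.5 * (K + K.T))
        clamp = max(gamma.max(), 0.0) * _EIG_CLAMP
        gamma = np.where(gamma > clamp, gamma, 0.0)
        self.gamma, self.Q = gamma, Q
        # b = Q' L^-1 Phi' y for every unit
        self.b = Q.T @ linalg.solve_triangular(self.L, Phi.T @ Y.T, lower=True)
        self.yy = np.einsum("ij,ij->i", Y, Y)
        self.B2 = (self.b**2).T  # (n_units, s)

    def sse_df(self, lambdas: np.ndarray):
        """Return SSE (n_units, n_lambda) and df (n_lambda,)."""
        W = 1.0 / (1.0 + np.outer(lambdas, self.gamma))  # (n_lambda, s)
        df = W.sum(axis=1)
        sse = self.yy[:, None] - 2.0 * self.B2 @ W.T + self.B2 @ (W**2).T
        return np.maximum(sse, 0.0), df

    def coefficients(self, lam: float) -> np.ndarray:
        """Coefficient matrix (n_units, s) at a single lambda."""
        w = 1.0 / (1.0 + lam * self.gamma)
        C = linalg.solve_triangular(
            self.L.T, self.Q @ (w[:, None] * self.b), lower=False
        )
        return C.T


def _gcv_from(sse, df, v):
    """GCV = v*SSE/(v-df)^2, +inf when the model saturates (df >= v)."""
    denom = v - df
    with np.errstate(divide="ignore", invalid="ignore"):
        gcv = v * sse / denom**2
    return np.where(denom > 1e-9, gcv, np.inf)


def fit_penalized(y, times, spec: BasisSpec, lam: float) -> FunctionalFit:
    """Fit one unit by penalized least squares at a fixed lambda."""
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.ndim != 1 or y.shape != times.shape:
        raise ValueError("y and times must be equal-length vectors")
    v = len(y)
    if v < 2:
        raise ValueError("need at least two observations")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    basis = build_basis(spec)
    Phi = basis.design_matrix(times)
    R = penalty_matrix(spec, basis)
    singular = False
    try:
        prof = _LambdaProfile(Phi, R, y[None, :])
        sse, df = prof.sse_df(np.array([lam]))
        sse, df = float(sse[0, 0]), float(df[0])
        c = prof.coefficients(lam)[0]
    except linalg.LinAlgError:
        # rank-deficient Phi'Phi (e.g. s > v): direct regularized solve
        singular = True
        A = Phi.T @ Phi + lam * R
        c, *_ = linalg.lstsq(A, Phi.T @ y)
        resid = y - Phi @ c
        sse = float(resid @ resid)
        df = float(np.trace(linalg.pinv(A) @ (Phi.T @ Phi)))
    fitted = Phi @ c
    residuals = y - fitted
    gcv = float(_gcv_from(np.array(sse), np.array(df), v))
    return FunctionalFit(c, float(lam), sse, df, gcv, residuals, singular)


def select_lambda(y, times, spec: BasisSpec, grid=None):
    """Exhaustive GCV search over lambda = 10^g on the exponent grid.

    Returns ``(lambda_star, gcv_star)``; ties break toward the smallest
    lambda (the grid is searched in increasing order).
    """
    exponents = _expand_grid(grid)
    lambdas = 10.0**exponents
    y = np.asarray(y, dtype=float)
    v = len(y)
    basis = build_basis(spec)
    Phi = basis.design_matrix(np.asarray(times, dtype=float))
    R = penalty_matrix(spec, basis)
    try:
        prof = _LambdaProfile(Phi, R, y[None, :])
        sse, df = prof.sse_df(lambdas)
        gcv = _gcv_from(sse[0], df, v)
    except linalg.LinAlgError:
        gcv = np.array([fit_penalized(y, times, spec, lam).gcv for lam in lambdas])
    if not np.isfinite(gcv).any():
        raise ValueError("GCV is infinite over the whole grid")
    j = int(np.argmin(gcv))
    return float(lambdas[j]), float(gcv[j])


def evaluate_curve(fit, spec: BasisSpec, times) -> np.ndarray:
    """Evaluate x(t) = Phi(times) c at the requested times."""
    c = fit.coefficients if isinstance(fit, FunctionalFit) else np.asarray(fit, float)
    return build_basis(spec).design_matrix(times) @ c


def _expand_grid(grid) -> np.ndarray:
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 3 and grid[2] > 0 and grid[1] > grid[0]:
        g_min, g_max, step = grid
        n = int(round((g_max - g_min) / step))
        return g_min + step * np.arange(n + 1)
    return np.sort(grid)


# ---------------------------------------------------------------------------
# Cohort-level grid search

@dataclass
class GridSearchResult:
    """Outcome of the (q, m, lambda) model search.

    ``table`` has one row per (q, m) with the TGCV-minimizing lambda;
    ``selected`` is the chosen (q, m) after any parsimony override.
    """

    table: pd.DataFrame
    selected: tuple
    lambda_: float
    tgcv: float
    override_applied: bool
    per_unit_gcv: dict

    def selected_row(self) -> pd.Series:
        q, m = self.selected
        match = self.table[(self.table["q"] == q) & (self.table["m"] == m)]
        return match.iloc[0]


def tgcv_grid_search(
    X,
    times,
    q_options=(5, 10, 15, 20),
    m_options=(4, 6),
    grid=None,
    domain=None,
    penalty_order: int = 2,
    parsimony_tol: float = 0.0,
) -> GridSearchResult:
    """Joint (q, m, lambda) selection minimizing TGCV = sum_i GCV_i.

    ``X`` is the (n_units, v) matrix of imputed series sharing ``times``.
    For each (q, m) a single cohort-wide lambda = 10^g minimizes the summed
    GCV; the returned model minimizes TGCV, except that with
    ``parsimony_tol > 0`` the simplest model (smallest s = q + m) whose
    TGCV is within the tolerance of the minimum is selected instead, the
    override being recorded.
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(times):
        raise ValueError("X must be (n_units, v) on a common time grid")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute first")
    if domain is None:
        domain = (float(times.min()), float(times.max()))
    exponents = _expand_grid(grid)
    lambdas = 10.0**exponents
    v = len(times)

    rows, per_unit = [], {}
    for q in q_options:
        for m in m_options:
            spec = BasisSpec(domain, q, m, penalty_order)
            basis = build_basis(spec)
            Phi = basis.design_matrix(times)
            R = penalty_matrix(spec, basis)
            try:
                prof = _LambdaProfile(Phi, R, X)
                sse, df = prof.sse_df(lambdas)
                gcv = _gcv_from(sse, df[None, :], v)  # (n_units, n_lambda)
            except linalg.LinAlgError:
                gcv = np.vstack(
                    [[fit_penalized(x, times, spec, lam).gcv for lam in lambdas] for x in X]
                )
            tgcv = gcv.sum(axis=0)
            if not np.isfinite(tgcv).any():
                raise ValueError(f"TGCV infinite over the grid for (q={q}, m={m})")
            j = int(np.argmin(tgcv))
            label = f"B-splines {(domain[1] - domain[0]) / (q + 1):g}-days"
            rows.append((label, m, q, float(lambdas[j]), float(tgcv[j])))
            per_unit[(q, m)] = gcv[:, j].copy()

    table = pd.DataFrame(rows, columns=["model_label", "m", "q", "lambda", "TGCV"])
    best = int(table["TGCV"].idxmin())
    selected = best
    override = False
    if parsimony_tol > 0:
        near = table[table["TGCV"] <= table.loc[best, "TGCV"] + parsimony_tol]
        sizes = near["q"] + near["m"]
        simplest = near.loc[sizes == sizes.min()]
        selected = int(simplest["TGCV"].idxmin())
        override = selected != best
    row = table.loc[selected]
    return GridSearchResult(
        table=table,
        selected=(int(row["q"]), int(row["m"])),
        lambda_=float(row["lambda"]),
        tgcv=float(row["TGCV"]),
        override_applied=override,
        per_unit_gcv=per_unit,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator

class PenalizedBSplineSmoother(TransformerMixin, BaseEstimator):
    """Transform daily series into penalized B-spline coefficients.

    Each sample (row of X) is a series observed on a common time grid; the
    transform output is the (n_samples, s) coefficient matrix of the shared
    penalized basis, the representation consumed by the fuzzy clustering
    step.

    Parameters
    ----------
    n_knots : int
        Number q of equally spaced interior knots.
    order : int
        Spline order m (degree + 1); cubic splines have order 4.
    penalty_order : int
        Derivative order of the roughness penalty (2 penalizes curvature).
    smoothing : "gcv" or float
        Either a fixed lambda, or "gcv" to pick the cohort-shared lambda
        minimizing the summed GCV over ``grid``.
    grid : (g_min, g_max, step) or array of exponents
        Search grid for lambda = 10^g when ``smoothing="gcv"``.
    times : array or None
        Observation times; defaults to 1..v at fit time.
    domain : (lo, hi) or None
        Basis domain; defaults to the span of ``times``.

    Attributes
    ----------
    coef_ : (n_samples, s) fitted coefficient matrix.
    lambda_ : selected smoothing parameter.
    df_ : effective degrees of freedom at ``lambda_``.
    sse_, gcv_ : per-sample residual sums of squares and GCV values.
    tgcv_ : summed GCV at ``lambda_``.
    basis_, spec_, penalty_ : basis evaluator, spec, and penalty matrix.
    """

    def __init__(
        self,
        n_knots: int = 15,
        order: int = 4,
        penalty_order: int = 2,
        smoothing="gcv",
        grid=DEFAULT_GRID,
        times=None,
        domain=None,
    ):
        self.n_knots = n_knots
        self.order = order
        self.penalty_order = penalty_order
        self.smoothing = smoothing
        self.grid = grid
        self.times = times
        self.domain = domain

    def _resolve_times(self, X):
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
        else:
            t = np.arange(1, X.shape[1] + 1, dtype=float)
        if len(t) != X.shape[1]:
            raise ValueError("times length does not match the number of columns")
        return t

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_timepoints)")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        t = self._resolve_times(X)
        domain = self.domain or (float(t.min()), float(t.max()))
        self.spec_ = BasisSpec(domain, self.n_knots, self.order, self.penalty_order)
        self.basis_ = build_basis(self.spec_)
        self.penalty_ = penalty_matrix(self.spec_, self.basis_)
        self.times_ = t
        Phi = self.basis_.design_matrix(t)
        v = len(t)

        if self.smoothing == "gcv":
            lambdas = 10.0 ** _expand_grid(self.grid)
        else:
            lambdas = np.array([float(self.smoothing)])

        try:
            prof = _LambdaProfile(Phi, self.penalty_, X)
            sse, df = prof.sse_df(lambdas)
            gcv = _gcv_from(sse, df[None, :], v)
            tgcv = gcv.sum(axis=0)
            j = int(np.argmin(tgcv)) if self.smoothing == "gcv" else 0
            self.lambda_ = float(lambdas[j])
            self.df_ = float(df[j])
            self.coef_ = prof.coefficients(self.lambda_)
            self.sse_ = sse[:, j].copy()
            self.gcv_ = gcv[:, j].copy()
        except linalg.LinAlgError:
            fits = [
                [fit_penalized(x, t, self.spec_, lam) for lam in lambdas] for x in X
            ]
            tgcv = np.array(
                [sum(row[j].gcv for row in fits) for j in range(len(lambdas))]
            )
            j = int(np.argmin(tgcv)) if self.smoothing == "gcv" else 0
            self.lambda_ = float(lambdas[j])
            self.coef_ = np.vstack([row[j].coefficients for row in fits])
            self.sse_ = np.array([row[j].sse for row in fits])
            self.gcv_ = np.array([row[j].gcv for row in fits])
            self.df_ = fits[0][j].df
        self.tgcv_ = float(tgcv[j])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Coefficients of new series at the fitted (basis, lambda)."""
        if not hasattr(self, "coef_"):
            raise ValueError("smoother is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of timepoints than at fit")
        Phi = self.basis_.design_matrix(self.times_)
        A = Phi.T @ Phi + self.lambda_ * self.penalty_
        return linalg.solve(A, Phi.T @ X.T, assume_a="pos").T

    def inverse_transform(self, C, times=None):
        """Evaluate coefficient rows back to curves on ``times``."""
        t = self.times_ if times is None else np.asarray(times, dtype=float)
        return np.asarray(C) @ self.basis_.design_matrix(t).T
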