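"""Classical and sparse supervised canonical correlation analysis.

The sparse supervised variant maximizes u' X' Y v subject to unit L2
bounds, L1 budgets ||u||_1 <= c_u and ||v||_1 <= c_v, and supervision
constraints restricting the supports to features associated with the
outcome.  Budgets are parameterized as c = max(1, penalty * sqrt(dim)),
so penalty = 1 is the unpenalized (SVD) limit and smaller penalties give
sparser loadings.  Optimization is by alternating soft-thresholded power
iterations with the threshold found by bisection on the L1 budget.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

__all__ = [
    "standardize_columns",
    "ClassicalCcaResult",
    "classical_cca",
    "supervision_sets",
    "soft_threshold",
    "CanonicalPair",
    "SparseCCA",
    "sparse_cca",
]


def standardize_columns(a):
    """Center to mean 0 and scale to sample SD 1 (ddof=1), column-wise."""
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    return (a - a.mean(axis=0)) / sd


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    w, q = linalg.eigh(mat)
    if w.min() < 1e-10:
        raise np.linalg.LinAlgError(
            "singular covariance block: use sparse_cca, which does not whiten"
        )
    return q @ np.diag(1.0 / np.sqrt(w)) @ q.T


@dataclass
class ClassicalCcaResult:
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    k: np.ndarray  # whitened cross-covariance
    e: np.ndarray  # left singular vectors
    f: np.ndarray  # right singular vectors
    d: np.ndarray  # singular values, descending
    u: np.ndarray  # canonical weights for X
    v: np.ndarray  # canonical weights for Y
    omega: np.ndarray  # X canonical variates
    xi: np.ndarray  # Y canonical variates

    @property
    def canonical_correlations(self) -> np.ndarray:
        return self.d


def classical_cca(X, Y) -> ClassicalCcaResult:
    """Classical CCA via SVD of the whitened cross-covariance.

    Requires n > p + q and nonsingular covariance blocks; the first
    canonical correlation is the leading singular value of
    K = Sxx^{-1/2} Sxy Syy^{-1/2}.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValueError("classical CCA needs n > p + q; use sparse_cca instead")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc / (n - 1)
    syy = Yc.T @ Yc / (n - 1)
    sxy = Xc.T @ Yc / (n - 1)
    sxx_i = _inv_sqrt(sxx)
    syy_i = _inv_sqrt(syy)
    k = sxx_i @ sxy @ syy_i
    e, d, ft = np.linalg.svd(k)
    f = ft.T
    u = sxx_i @ e
    v = syy_i @ f
    return ClassicalCcaResult(
        sigma_xx=sxx, sigma_yy=syy, sigma_xy=sxy, k=k, e=e, f=f, d=d,
        u=u, v=v, omega=Xc @ u, xi=Yc @ v,
    )


def supervision_sets(X, Y, z, q_frac: float):
    """Indices of features most associated with the outcome, per view.

    Association is the two-sample pooled t statistic against the binary
    outcome z; the top ``ceil(q_frac * dim)`` features by |t| are kept.
    ``q_frac=1`` keeps everything (the pipeline default, since inputs are
    already DE-selected).
    """
    if not 0.0 < q_frac <= 1.0:
        raise ValueError("q_frac must lie in (0, 1]")

    def tstats(a):
        a = np.asarray(a, dtype=float)
        zz = np.asarray(z)
        g1 = a[zz == 1]
        g0 = a[zz == 0]
        n1, n0 = g1.shape[0], g0.shape[0]
        sp2 = (
            ((g1 - g1.mean(0)) ** 2).sum(0) + ((g0 - g0.mean(0)) ** 2).sum(0)
        ) / (n1 + n0 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (g1.mean(0) - g0.mean(0)) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        return np.where(np.isnan(t), 0.0, t)

    def top(t):
        keep = int(np.ceil(q_frac * t.size))
        order = np.argsort(-np.abs(t), kind="stable")
        return np.sort(order[:keep])

    return top(tstats(X)), top(tstats(Y))


def soft_threshold(a, c):
    """sign(a) * max(|a| - c, 0), elementwise."""
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - c, 0.0)


def _l1_project(a: np.ndarray, c: float, tol: float = 1e-8, max_steps: int = 50):
    """Soft-threshold and L2-normalize ``a`` so the L1 norm is <= c.

    Returns the normalized vector.  The threshold is 0 when the budget is
    slack, otherwise found by bisection.
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("all-zero update vector")
    u = a / norm
    if np.abs(u).sum() <= c + tol:
        return u
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        su = soft_threshold(a, mid)
        nn = np.linalg.norm(su)
        l1 = np.abs(su).sum() / nn if nn > 0 else 0.0
        if l1 > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    su = soft_threshold(a, hi)
    return su / np.linalg.norm(su)


@dataclass
class CanonicalPair:
    """First sparse canonical pair with supports and provenance."""

    u: np.ndarray
    v: np.ndarray
    c_u: float
    c_v: float
    q_u: np.ndarray
    q_v: np.ndarray
    correlation: float
    x_ids: list[str] = field(default_factory=list)
    y_ids: list[str] = field(default_factory=list)
    objective_path: list[float] = field(default_factory=list)

    @property
    def selected_x(self) -> np.ndarray:
        return np.flatnonzero(self.u != 0)

    @property
    def selected_y(self) -> np.ndarray:
        return np.flatnonzero(self.v != 0)

    @property
    def selected_x_ids(self) -> list[str]:
        ids = self.x_ids or [f"X{i}" for i in range(self.u.size)]
        return [ids[i] for i in self.selected_x]

    @property
    def selected_y_ids(self) -> list[str]:
        ids = self.y_ids or [f"Y{i}" for i in range(self.v.size)]
        return [ids[i] for i in self.selected_y]

    def loadings_frame(self) -> pd.DataFrame:
        ids = (self.x_ids or [f"X{i}" for i in range(self.u.size)]) + (
            self.y_ids or [f"Y{i}" for i in range(self.v.size)]
        )
        weights = np.concatenate([self.u, self.v])
        kinds = ["miRNA"] * self.u.size + ["mRNA"] * self.v.size
        return pd.DataFrame(
            {"feature_id": ids, "kind": kinds, "weight": weights,
             "selected": weights != 0}
        )


class SparseCCA(BaseEstimator):
    """Sparse supervised CCA (first canonical pair).

    Parameters
    ----------
    penalty_u, penalty_v : float in (0, 1]
        L1 budget fractions; the budgets are c = max(1, penalty * sqrt(dim)).
    q_frac : float in (0, 1]
        Fraction of features admitted to the supervision sets by univariate
        association with the outcome (1 keeps all features).
    max_iter, tol : alternating-update controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    u_, v_ : sparse loading vectors (largest-|u| entry made positive)
    correlation_ : Pearson correlation of the canonical variates
    selected_x_, selected_y_ : support index arrays
    objective_path_ : u' X'Y v after each alternating iteration
    """

    def __init__(self, penalty_u: float = 0.3, penalty_v: float = 0.5,
                 q_frac: float = 1.0, max_iter: int = 50, tol: float = 1e-6):
        self.penalty_u = penalty_u
        self.penalty_v = penalty_v
        self.q_frac = q_frac
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y, z=None):
        if not (0 < self.penalty_u <= 1 and 0 < self.penalty_v <= 1):
            raise ValueError("penalties must lie in (0, 1]")
        x_ids = list(X.columns) if isinstance(X, pd.DataFrame) else []
        y_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else []
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        q = Y.shape[1]
        c_u = max(1.0, self.penalty_u * np.sqrt(p))
        c_v = max(1.0, self.penalty_v * np.sqrt(q))
        if z is not None and self.q_frac < 1.0:
            q_u, q_v = supervision_sets(X, Y, z, self.q_frac)
        else:
            if self.q_frac < 1.0:
                raise ValueError("q_frac < 1 requires an outcome vector z")
            q_u, q_v = np.arange(p), np.arange(q)

        M = X.T @ Y
        mask_u = np.zeros(p, dtype=bool)
        mask_u[q_u] = True
        mask_v = np.zeros(q, dtype=bool)
        mask_v[q_v] = True
        M = M * mask_u[:, None] * mask_v[None, :]
        if not np.any(M):
            raise ValueError("cross-covariance is all zero after supervision restriction")

        # initialize v from the leading right singular vector of restricted M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        path: list[float] = []
        for it in range(self.max_iter):
            u_new = _l1_project(M @ v, c_u)
            v_new = _l1_project(M.T @ u_new, c_v)
            path.append(float(u_new @ M @ v_new))
            delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
            u, v = u_new, v_new
            if delta < self.tol:
                break

        # sign convention: largest-|u| entry positive (flip both to keep
        # the objective invariant)
        top = np.argmax(np.abs(u))
        if u[top] < 0:
            u, v = -u, -v
        omega = X @ u
        xi = Y @ v
        corr = float(np.corrcoef(omega, xi)[0, 1]) if omega.std() > 0 and xi.std() > 0 else 0.0

        self.u_, self.v_ = u, v
        self.c_u_, self.c_v_ = c_u, c_v
        self.q_u_, self.q_v_ = q_u, q_v
        self.correlation_ = corr
        self.selected_x_ = np.flatnonzero(u != 0)
        self.selected_y_ = np.flatnonzero(v != 0)
        self.objective_path_ = path
        self.n_iter_ = len(path)
        self.x_ids_ = x_ids
        self.y_ids_ = y_ids
        return self

    def canonical_pair_(self) -> CanonicalPair:
        return CanonicalPair(
            u=self.u_, v=self.v_, c_u=self.c_u_, c_v=self.c_v_,
            q_u=self.q_u_, q_v=self.q_v_, correlation=self.correlation_,
            x_ids=self.x_ids_, y_ids=self.y_ids_,
            objective_path=self.objective_path_,
        )


def sparse_cca(X, Y, z=None, penalty_u: float = 0.3, penalty_v: float = 0.5,
               q_frac: float = 1.0, max_iter: int = 50, tol: float = 1e-6) -> CanonicalPair:
    """Functional wrapper around :class:`SparseCCA`."""
    est = SparseCCA(penalty_u, penalty_v, q_frac, max_iter, tol).fit(X, Y, z)
    return est.canonical_pair_()
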