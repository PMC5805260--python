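"""Sparse partial correlation estimation (SPACE).

All p node-wise regressions X_i = sum_{j != i} beta_j^(i) X_j + eps_i are
fit jointly under the symmetric reparameterization

    beta_j^(i) = rho_ij * sqrt(sigma^jj / sigma^ii),

so the free parameters are the partial correlations rho_ij themselves.  The
objective is  (1/2) sum_i RSS_i + n * lam1 * sum_{i<j} |rho_ij|, minimized
by cyclic coordinate descent over pairs with the conditional-precision
weights sigma^ii refreshed between passes.  The default penalty follows the
standard-normal-quantile rule lam1 = Phi^{-1}(1 - alpha / (2 p^2)) / sqrt(n).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "default_lam1",
    "SpacePartialCorrelation",
    "space_fit",
    "neighborhood_rho",
    "edges_from_rho",
]


def default_lam1(n: int, p: int, alpha: float = 1.0) -> float:
    """Default L1 penalty: Phi^{-1}(1 - alpha / (2 p^2)) / sqrt(n)."""
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 and p >= 2")
    tail = alpha / (2.0 * p * p)
    if not 0.0 < tail < 1.0:
        raise ValueError("alpha / (2 p^2) must lie in (0, 1)")
    return float(stats.norm.ppf(1.0 - tail) / np.sqrt(n))


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


class SpacePartialCorrelation(BaseEstimator):
    """Joint sparse estimator of all pairwise partial correlations.

    Parameters
    ----------
    lam1 : float or None
        L1 penalty on the rho parameters; ``None`` selects
        :func:`default_lam1` with the given ``alpha`` at fit time.
    alpha : float
        Tail constant for the automatic penalty.
    outer_iters : int
        Number of (coordinate-descent, sigma-update) alternations.
    tol, max_sweeps : coordinate-descent convergence controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    rho_ : symmetric p x p partial-correlation estimates, unit diagonal
    beta_ : implied regression coefficients, beta_[i, j] = beta_j^(i)
    sigma_ : per-node conditional precision weights sigma^ii
    edges_ : DataFrame of nonzero off-diagonal pairs with sign
    lam1_ : penalty actually used
    objective_path_ : objective value after each coordinate sweep
    """

    def __init__(self, lam1: float | None = None, alpha: float = 1.0,
                 outer_iters: int = 2, tol: float = 1e-6, max_sweeps: int = 500):
        self.lam1 = lam1
        self.alpha = alpha
        self.outer_iters = outer_iters
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in the input")
        n, p = X.shape
        X = X - X.mean(axis=0)  # columns centered to the column mean
        lam1 = default_lam1(n, p, self.alpha) if self.lam1 is None else float(self.lam1)
        if lam1 < 0:
            raise ValueError("lam1 must be >= 0")

        G = X.T @ X
        pen = n * lam1
        rho = np.zeros((p, p))
        B = np.zeros((p, p))  # B[i, j] = beta_j^(i)
        sigma = np.ones(p)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        path: list[float] = []

        def objective():
            rss = 0.0
            for i in range(p):
                bi = B[i]
                rss += G[i, i] - 2.0 * bi @ G[i] + bi @ G @ bi
            l1 = sum(abs(rho[i, j]) for i, j in pairs)
            return 0.5 * rss + pen * l1

        for _ in range(self.outer_iters):
            s = np.sqrt(sigma)
            for _sweep in range(self.max_sweeps):
                delta = 0.0
                for i, j in pairs:
                    s_ij = s[j] / s[i]  # sqrt(sigma_jj / sigma_ii)
                    s_ji = 1.0 / s_ij
                    a = s_ij * s_ij * G[j, j] + s_ji * s_ji * G[i, i]
                    xjri = G[j, i] - G[j] @ B[i]
                    xirj = G[i, j] - G[i] @ B[j]
                    b = s_ij * xjri + s_ji * xirj + rho[i, j] * a
                    new = _soft(b, pen) / a
                    if new != rho[i, j]:
                        delta = max(delta, abs(new - rho[i, j]))
                        rho[i, j] = rho[j, i] = new
                        B[i, j] = new * s_ij
                        B[j, i] = new * s_ji
                path.append(objective())
                if delta < self.tol:
                    break
            # refresh the conditional precision weights from the fit
            for i in range(p):
                bi = B[i]
                rss_i = G[i, i] - 2.0 * bi @ G[i] + bi @ G @ bi
                sigma[i] = n / max(rss_i, 1e-12)

        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        self.rho_ = rho
        self.beta_ = B
        self.sigma_ = sigma
        self.lam1_ = lam1
        self.objective_path_ = path
        self.feature_names_ = list(feature_names) if feature_names else [
            f"V{i}" for i in range(p)
        ]
        self.edges_ = edges_from_rho(rho, self.feature_names_)
        return self


def edges_from_rho(rho: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Edge list of the nonzero off-diagonal support of a rho matrix."""
    rows = []
    p = rho.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if rho[i, j] != 0.0:
                rows.append(
                    {"node_i": names[i], "node_j": names[j],
                     "weight": rho[i, j], "sign": int(np.sign(rho[i, j])),
                     "directed": False, "source": "SPACE"}
                )
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign",
                                       "directed", "source"])


def space_fit(X, lam1: float | None = None, outer_iters: int = 2,
              alpha: float = 1.0, **kwargs) -> SpacePartialCorrelation:
    """Functional wrapper around :class:`SpacePartialCorrelation`."""
    return SpacePartialCorrelation(
        lam1=lam1, alpha=alpha, outer_iters=outer_iters, **kwargs
    ).fit(X)


def neighborhood_rho(beta: np.ndarray) -> np.ndarray:
    """Combine per-node regression coefficients into partial correlations.

    rho_ij = sign(beta_j^(i)) * sqrt(beta_j^(i) * beta_i^(j)); pairs whose
    two coefficients disagree in sign are set to 0 with a warning, since the
    product under the root must be non-negative.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    rho = np.eye(p)
    discordant = 0
    for i in range(p):
        for j in range(i + 1, p):
            prod = beta[i, j] * beta[j, i]
            if prod > 0:
                rho[i, j] = rho[j, i] = np.sign(beta[i, j]) * np.sqrt(prod)
            elif prod < 0:
                discordant += 1
    if discordant:
        warnings.warn(
            f"{discordant} pair(s) had discordant coefficient signs; "
            "their partial correlations were set to 0"
        )
    return rho
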