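"""Shooting (cyclic coordinate descent) solver for the lasso.

The objective is ||y - X b||^2 + n * lam * ||b||_1: the interface-level
penalty ``lam`` multiplies the L1 norm after internal scaling by the sample
size, so that values quoted on the conventional scale (e.g. 0.2) behave the
same regardless of n.  Solutions are computed on the Gram matrix, which is
what the Bayesian-network search needs: it scores thousands of (node,
candidate-parent-set) pairs against a single precomputed X'X.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["shooting_lasso", "shooting_gram", "lasso_objective_gram", "batch_lasso_scores"]


@njit(cache=False)
def _cd_gram(G, b, half_pen, beta, tol, max_iter):
    k = b.shape[0]
    for _ in range(max_iter):
        delta = 0.0
        for j in range(k):
            gj = G[j]
            z = b[j] - np.dot(gj, beta) + gj[j] * beta[j]
            old = beta[j]
            if z > half_pen:
                new = (z - half_pen) / gj[j]
            elif z < -half_pen:
                new = (z + half_pen) / gj[j]
            else:
                new = 0.0
            if new != old:
                beta[j] = new
                d = abs(new - old)
                if d > delta:
                    delta = d
        if delta < tol:
            break
    return beta


def shooting_gram(G, b, penalty, beta0=None, tol: float = 1e-10, max_iter: int = 10000):
    """Minimize b'Gb-style lasso on the Gram scale.

    Solves min_beta  beta' G beta - 2 b' beta + penalty * ||beta||_1
    (equivalently ||y - X beta||^2 up to the constant y'y with G = X'X and
    b = X'y).
    """
    G = np.ascontiguousarray(G, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    beta = np.zeros(b.shape[0]) if beta0 is None else np.asarray(beta0, dtype=np.float64).copy()
    if b.size == 0:
        return beta
    return _cd_gram(G, b, penalty / 2.0, beta, tol, max_iter)


def lasso_objective_gram(G, b, yty, penalty, beta) -> float:
    """||y - X beta||^2 + penalty * ||beta||_1 on the Gram scale."""
    if beta.size == 0:
        return float(yty)
    return float(yty - 2.0 * b @ beta + beta @ G @ beta + penalty * np.abs(beta).sum())


@njit(cache=False)
def _batch_scores(G, cand, targets, half_pen, tol, max_iter):
    """Lasso scores for several targets sharing one candidate-parent set.

    Returns, per target j, min_b ||x_j - X_cand b||^2 + 2*half_pen*||b||_1
    computed on the Gram scale.  Sharing the extracted sub-Gram across
    targets is what makes scoring all successors of one search state cheap.
    """
    d = cand.shape[0]
    m = targets.shape[0]
    out = np.empty(m)
    sub = np.empty((d, d))
    for a in range(d):
        for b in range(d):
            sub[a, b] = G[cand[a], cand[b]]
    bv = np.empty(d)
    beta = np.empty(d)
    for t in range(m):
        j = targets[t]
        if d == 0:
            out[t] = G[j, j]
            continue
        for a in range(d):
            bv[a] = G[cand[a], j]
            beta[a] = 0.0
        for _ in range(max_iter):
            delta = 0.0
            for a in range(d):
                z = bv[a] - np.dot(sub[a], beta) + sub[a, a] * beta[a]
                old = beta[a]
                if z > half_pen:
                    new = (z - half_pen) / sub[a, a]
                elif z < -half_pen:
                    new = (z + half_pen) / sub[a, a]
                else:
                    new = 0.0
                if new != old:
                    beta[a] = new
                    dd = abs(new - old)
                    if dd > delta:
                        delta = dd
            if delta < tol:
                break
        obj = G[j, j]
        l1 = 0.0
        for a in range(d):
            obj -= 2.0 * bv[a] * beta[a]
            l1 += abs(beta[a])
            acc = 0.0
            for b in range(d):
                acc += sub[a, b] * beta[b]
            obj += beta[a] * acc
        out[t] = obj + 2.0 * half_pen * l1
    return out


def batch_lasso_scores(G, cand, targets, penalty, tol: float = 1e-10, max_iter: int = 10000):
    """Vectorized lasso scores for many targets against one candidate set."""
    cand = np.ascontiguousarray(cand, dtype=np.int64)
    targets = np.ascontiguousarray(targets, dtype=np.int64)
    return _batch_scores(
        np.ascontiguousarray(G, dtype=np.float64), cand, targets,
        penalty / 2.0, tol, max_iter,
    )


def shooting_lasso(y, X, lam: float, tol: float = 1e-10, max_iter: int = 10000):
    """Lasso coefficients for min ||y - X b||^2 + n * lam * ||b||_1.

    ``lam = 0`` recovers the OLS solution for a full-rank design; large
    ``lam`` shrinks every coefficient to exactly zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite values in the lasso inputs")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = y.shape[0]
    G = X.T @ X
    b = X.T @ y
    return shooting_gram(G, b, n * lam, tol=tol, max_iter=max_iter)
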