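"""Sparse Bayesian-network structure learning by A* search with lasso scores.

The DAG is recovered through its topological ordering: a search state is
the subset Q_s of variables whose ordering is fixed, the cost of appending
node v to Q_s is its lasso score with Q_s as candidate parents,

    LassoScore(v | C) = min_b ||x_v - X_C b||^2 + lam * n * ||b||_1,

and the admissible heuristic for a state is the sum, over unordered nodes,
of their scores with *all* other nodes as candidates (enlarging a candidate
set can never increase a lasso score, so this relaxation is a lower bound).
With an unlimited queue the search is exact; a size-limited priority queue
(the study-scale default keeps the 3000 best frontier states by f = g + h)
trades optimality for speed on larger node sets.  Per-node noise is modeled
as standard Gaussian, which is why inputs must be standardized.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lasso import batch_lasso_scores, lasso_objective_gram, shooting_gram

__all__ = ["DagModel", "AStarLasso", "astar_lasso", "lasso_score"]


def lasso_score(j: int, candidates, X, lam: float) -> float:
    """Optimal penalized objective for one node given candidate parents."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    cand = np.asarray(sorted(candidates), dtype=int)
    G = X.T @ X
    sub = G[np.ix_(cand, cand)]
    b = G[cand, j]
    beta = shooting_gram(sub, b, n * lam)
    return lasso_objective_gram(sub, b, G[j, j], n * lam, beta)


@dataclass
class DagModel:
    """A learned DAG: ordering, parent sets, coefficients, and total score."""

    order: list[int]
    parents: dict[int, list[int]]
    edges: pd.DataFrame  # parent, child, coefficient
    score: float
    lam: float
    queue_limit: int | None
    node_names: list[str] = field(default_factory=list)

    def edge_pairs(self) -> set[tuple[int, int]]:
        return {(int(r["parent_index"]), int(r["child_index"]))
                for _, r in self.edges.iterrows()}


class AStarLasso(BaseEstimator):
    """A*-lasso Bayesian network estimator.

    Parameters
    ----------
    lam : float
        L1 penalty on each node's parent coefficients (interface scale; the
        recommended value is 0.2).
    queue_limit : int or None
        Maximum frontier size; ``None`` (or a value >= the full state
        space) makes the search exact.
    max_nodes : int
        Guard on the number of variables; the subset state space grows as
        2^p, so larger problems must set ``allow_large=True`` explicitly.
    allow_large : bool
        Permit p > max_nodes (relies on queue truncation for tractability).

    Attributes (after :meth:`fit`)
    ------------------------------
    order_ : optimal (or best-found) topological ordering
    parents_ : dict node -> list of parent nodes (nonzero lasso coefficients)
    edges_ : DataFrame with parent/child names and coefficients
    coef_ : p x p matrix, coef_[child, parent]
    score_ : total accumulated lasso score of the returned ordering
    n_expanded_ : number of states expanded by the search
    """

    def __init__(self, lam: float = 0.2, queue_limit: int | None = 3000,
                 max_nodes: int = 25, allow_large: bool = False,
                 standardized_rtol: float = 0.05):
        self.lam = lam
        self.queue_limit = queue_limit
        self.max_nodes = max_nodes
        self.allow_large = allow_large
        self.standardized_rtol = standardized_rtol

    def _check_standardized(self, X: np.ndarray) -> None:
        scale = np.abs(X).max() + 1e-12
        if np.abs(X.mean(axis=0)).max() > 1e-6 * scale:
            raise ValueError("columns must be centered (standardize the data first)")
        sd = X.std(axis=0, ddof=1)
        if np.abs(sd - 1.0).max() > self.standardized_rtol:
            raise ValueError("columns must have unit standard deviation")

    def fit(self, X, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in the input")
        n, p = X.shape
        if p > 1:
            self._check_standardized(X)
        if p > self.max_nodes and not self.allow_large:
            raise ValueError(
                f"p={p} exceeds max_nodes={self.max_nodes}; "
                "set allow_large=True to search anyway"
            )
        names = list(feature_names) if feature_names else [f"V{i}" for i in range(p)]

        G = np.ascontiguousarray(X.T @ X)
        pen = n * self.lam
        memo: dict[tuple[int, int], float] = {}

        def _bits(mask: int) -> list[int]:
            return [k for k in range(p) if (mask >> k) & 1]

        def score(j: int, mask: int) -> float:
            key = (j, mask)
            got = memo.get(key)
            if got is None:
                got = float(
                    batch_lasso_scores(G, np.array(_bits(mask)), np.array([j]), pen)[0]
                )
                memo[key] = got
            return got

        def score_successors(mask: int, targets: list[int]) -> list[float]:
            # all successors of one state share the candidate set: score the
            # uncached targets in one batched solve
            todo = [j for j in targets if (j, mask) not in memo]
            if todo:
                vals = batch_lasso_scores(G, np.array(_bits(mask)), np.array(todo), pen)
                for j, v in zip(todo, vals):
                    memo[(j, mask)] = float(v)
            return [memo[(j, mask)] for j in targets]

        full = (1 << p) - 1
        full_scores = np.array([score(j, full & ~(1 << j)) for j in range(p)])
        h_total = float(full_scores.sum())

        def h(mask: int) -> float:
            # sum of full-candidate scores over nodes not yet ordered
            out = h_total
            m = mask
            while m:
                k = (m & -m).bit_length() - 1
                out -= full_scores[k]
                m &= m - 1
            return out

        # heap entries: (f, p - |Q_s|, mask, g, order); ties break toward
        # lower f, then larger |Q_s|, then the smaller subset key
        heap = [(h(0), p, 0, 0.0, ())]
        best_g: dict[int, float] = {0: 0.0}
        expanded = 0
        goal_order: tuple[int, ...] | None = None
        goal_g = np.inf
        limit = self.queue_limit if self.queue_limit is not None else None
        while heap:
            f, _, mask, g, order = heapq.heappop(heap)
            if g > best_g.get(mask, np.inf) + 1e-12:
                continue  # stale entry superseded by a cheaper path
            if mask == full:
                goal_order, goal_g = order, g
                break
            expanded += 1
            targets = [j for j in range(p) if not mask & (1 << j)]
            succ_scores = score_successors(mask, targets)
            size2 = p - bin(mask).count("1") - 1
            for j, sc in zip(targets, succ_scores):
                g2 = g + sc
                m2 = mask | (1 << j)
                if g2 < best_g.get(m2, np.inf) - 1e-12:
                    best_g[m2] = g2
                    heapq.heappush(heap, (g2 + h(m2), size2, m2, g2, order + (j,)))
            if limit is not None and len(heap) > limit:
                heap = heapq.nsmallest(limit, heap)
                heapq.heapify(heap)
        if goal_order is None:
            raise RuntimeError("search exhausted the frontier without reaching the goal")

        # materialize edges: refit each node's lasso on its full predecessor set
        parents: dict[int, list[int]] = {}
        coef = np.zeros((p, p))
        rows = []
        pred_mask = 0
        for j in goal_order:
            cand = [k for k in range(p) if (pred_mask >> k) & 1]
            if cand:
                idx = np.asarray(cand, dtype=int)
                sub = np.ascontiguousarray(G[np.ix_(idx, idx)])
                bv = np.ascontiguousarray(G[idx, j])
                beta = shooting_gram(sub, bv, pen)
                pa = [cand[t] for t in range(len(cand)) if beta[t] != 0.0]
                for t, k in enumerate(cand):
                    if beta[t] != 0.0:
                        coef[j, k] = beta[t]
                        rows.append(
                            {"node_i": names[k], "node_j": names[j],
                             "parent_index": k, "child_index": j,
                             "weight": beta[t], "sign": int(np.sign(beta[t])),
                             "directed": True, "source": "ASTAR"}
                        )
            else:
                pa = []
            parents[j] = pa
            pred_mask |= 1 << j

        self.order_ = list(goal_order)
        self.parents_ = parents
        self.coef_ = coef
        self.score_ = float(goal_g)
        self.n_expanded_ = expanded
        self.feature_names_ = names
        self.edges_ = pd.DataFrame(
            rows, columns=["node_i", "node_j", "parent_index", "child_index",
                           "weight", "sign", "directed", "source"]
        )
        return self

    def dag_model_(self) -> DagModel:
        return DagModel(
            order=self.order_, parents=self.parents_, edges=self.edges_,
            score=self.score_, lam=self.lam, queue_limit=self.queue_limit,
            node_names=self.feature_names_,
        )


def astar_lasso(X, lam: float = 0.2, queue_limit: int | None = 3000,
                **kwargs) -> DagModel:
    """Functional wrapper around :class:`AStarLasso`."""
    return AStarLasso(lam=lam, queue_limit=queue_limit, **kwargs).fit(X).dag_model_()
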