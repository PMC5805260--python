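"""All-pairs Pearson correlation network with BH-adjusted significance.

This is the baseline the sparse methods are compared against: every
off-diagonal pair is tested with the t transform
t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom, and the
Benjamini-Hochberg adjustment is applied across the full family of
p (p - 1) / 2 tests (within- and cross-set pairs pooled).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .de import bh_adjust

__all__ = ["PearsonCorrelationNetwork", "pearson_network"]


class PearsonCorrelationNetwork(BaseEstimator):
    """Pairwise Pearson correlation network estimator.

    Attributes (after :meth:`fit`)
    ------------------------------
    r_ : symmetric correlation matrix
    p_ : raw two-sided p-values (diagonal 0, excluded from testing)
    p_adjusted_ : BH-adjusted p-values over the off-diagonal family
    edges_ : DataFrame of pairs with adjusted p < alpha
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 4:
            raise ValueError("need at least 4 samples")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("zero-variance column")
        names = list(feature_names) if feature_names else [f"V{i}" for i in range(p)]

        r = np.corrcoef(X, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        iu = np.triu_indices(p, k=1)
        rv = r[iu]
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rv * np.sqrt(df / (1.0 - rv ** 2))
        praw = np.where(np.abs(rv) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
        padj = bh_adjust(praw)

        pmat = np.zeros((p, p))
        qmat = np.zeros((p, p))
        pmat[iu] = praw
        qmat[iu] = padj
        pmat += pmat.T
        qmat += qmat.T

        rows = []
        for (i, j, pr, pa) in zip(iu[0], iu[1], praw, padj):
            if pa < self.alpha:
                rows.append(
                    {"node_i": names[i], "node_j": names[j], "weight": r[i, j],
                     "sign": int(np.sign(r[i, j])), "p": pr, "p_adjusted": pa,
                     "directed": False, "source": "PEARSON"}
                )
        self.r_ = r
        self.p_ = pmat
        self.p_adjusted_ = qmat
        self.feature_names_ = names
        self.edges_ = pd.DataFrame(
            rows, columns=["node_i", "node_j", "weight", "sign", "p",
                           "p_adjusted", "directed", "source"]
        )
        return self


def pearson_network(X, alpha: float = 0.01, feature_names=None) -> PearsonCorrelationNetwork:
    """Functional wrapper around :class:`PearsonCorrelationNetwork`."""
    return PearsonCorrelationNetwork(alpha=alpha).fit(X, feature_names=feature_names)
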