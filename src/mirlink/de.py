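"""Two-group differential expression with empirical-Bayes moderated t.

Per feature, an ordinary least-squares fit on [intercept, group] gives the
case-minus-control effect and a residual variance s_g^2 on d_g = n - 2
degrees of freedom.  The variances are shrunk toward a global prior by the
standard empirical-Bayes construction: the prior degrees of freedom d0 and
prior variance s0^2 are obtained by matching the marginal moments of
log s_g^2 (Fisher-digamma method), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t of the effect is referred to a t distribution on
d0 + d_g degrees of freedom.  Raw p-values are adjusted by the
Benjamini-Hochberg step-up procedure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .containers import CASE, ExpressionMatrix, GroupDesign

__all__ = [
    "DEResult",
    "ModeratedTTest",
    "fit_group_model",
    "ebayes_moderate",
    "bh_adjust",
    "select_de",
    "run_de",
    "posterior_variance",
]


def _group_lm(V: np.ndarray, z: np.ndarray):
    """Per-feature OLS on [intercept, group indicator].

    V is features x samples (complete); z is the binary outcome.  Returns
    (effect, s2, d, v) where effect is the group coefficient
    (case - control), s2 the residual variance, d = n - 2 the residual df,
    and v the unscaled variance of the effect (1/n1 + 1/n0).
    """
    z = np.asarray(z)
    n1 = int(z.sum())
    n0 = int((1 - z).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need at least 2 samples")
    case = V[:, z == 1]
    ctrl = V[:, z == 0]
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    d = n1 + n0 - 2
    s2 = ss / d
    v = 1.0 / n1 + 1.0 / n0
    return effect, s2, d, v


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, d: float):
    """Moment-match (d0, s0^2) from the marginal distribution of log s^2."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def posterior_variance(s2, d, d0, s02):
    """Shrunken variance (d0*s02 + d*s2) / (d0 + d); s02 when d0 is infinite."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + d * s2) / (d0 + d)


@dataclass
class DEResult:
    """Per-feature moderated-t statistics plus the global prior."""

    table: pd.DataFrame  # effect, s2, df, s2_post, t, p, p_adjusted
    d0: float
    s0_squared: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path, alpha: float = 0.01) -> None:
        out = self.table.copy()
        out["selected"] = out["p_adjusted"] < alpha
        out.to_csv(path, sep="\t", index_label="feature_id")


def fit_group_model(m: ExpressionMatrix, design: GroupDesign):
    """OLS group-model fits for a complete (imputed) matrix.

    Returns a DataFrame with columns effect, s2, df, v indexed by feature.
    """
    if m.missing_mask.any():
        raise ValueError("fit_group_model requires a complete (imputed) matrix")
    z = np.array([1 if design.group[s] == CASE else 0 for s in m.sample_ids])
    effect, s2, d, v = _group_lm(m.values, z)
    return pd.DataFrame(
        {"effect": effect, "s2": s2, "df": float(d), "v": v}, index=m.feature_ids
    )


def ebayes_moderate(fits: pd.DataFrame) -> DEResult:
    """Empirical-Bayes moderation of per-feature variances.

    ``fits`` must carry columns effect, s2, df, v.  If every s2 is zero the
    ordinary t is returned with a warning; if the estimated d0 is infinite
    all posterior variances equal s0^2.
    """
    if len(fits) < 10:
        warnings.warn("fewer than 10 features: prior estimates may be unstable")
    effect = fits["effect"].to_numpy()
    s2 = fits["s2"].to_numpy()
    d = float(fits["df"].iloc[0])
    v = fits["v"].to_numpy()

    if np.all(s2 == 0):
        warnings.warn("all residual variances are zero; falling back to ordinary t")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(s2 * v)
        t = np.where(np.isnan(t), 0.0, t)
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), d))
        table = pd.DataFrame(
            {"effect": effect, "s2": s2, "df": d, "s2_post": s2, "t": t,
             "p": p, "p_adjusted": bh_adjust(p)},
            index=fits.index,
        )
        return DEResult(table, d0=0.0, s0_squared=0.0)

    d0, s02 = _fit_f_dist(s2, d)
    s2_post = posterior_variance(s2, d, d0, s02)
    df_total = np.inf if np.isinf(d0) else d0 + d
    t = effect / np.sqrt(s2_post * v)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"effect": effect, "s2": s2, "df": d, "s2_post": s2_post, "t": t,
         "p": p, "p_adjusted": bh_adjust(p)},
        index=fits.index,
    )
    return DEResult(table, d0=d0, s0_squared=s02)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def select_de(de: DEResult, alpha: float = 0.01) -> list[str]:
    """Feature ids with adjusted p strictly below ``alpha``, order preserved."""
    flag = de.table["p_adjusted"] < alpha
    return list(de.table.index[flag])


def run_de(m: ExpressionMatrix, design: GroupDesign, alpha: float = 0.01):
    """Fit, moderate, and select for one expression layer."""
    de = ebayes_moderate(fit_group_model(m, design))
    return de, select_de(de, alpha)


class ModeratedTTest(BaseEstimator):
    """scikit-learn style two-group moderated-t selector.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance threshold for :meth:`get_support`.

    Attributes (after :meth:`fit`)
    ------------------------------
    effect_, s2_, t_, p_, p_adjusted_ : ndarray per feature
    d0_, s0_squared_ : float, the empirical-Bayes prior
    selected_ : boolean mask of features with adjusted p < alpha
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        effect, s2, d, v = _group_lm(X.T, y)
        res = ebayes_moderate(
            pd.DataFrame({"effect": effect, "s2": s2, "df": float(d), "v": v})
        )
        tab = res.table
        self.effect_ = tab["effect"].to_numpy()
        self.s2_ = tab["s2"].to_numpy()
        self.s2_post_ = tab["s2_post"].to_numpy()
        self.t_ = tab["t"].to_numpy()
        self.p_ = tab["p"].to_numpy()
        self.p_adjusted_ = tab["p_adjusted"].to_numpy()
        self.d0_ = res.d0
        self.s0_squared_ = res.s0_squared
        self.selected_ = self.p_adjusted_ < self.alpha
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.selected_

    def transform(self, X):
        return np.asarray(X)[:, self.selected_]
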