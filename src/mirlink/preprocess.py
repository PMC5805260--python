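"""Microarray preprocessing: replicate collapsing, presence/missingness
filters, outlier masking, quantile normalization, and kNN imputation.

The pipeline order is fixed: collapse -> filter -> mask_outliers ->
quantile_normalize -> knn_impute.  Filters act on absence/missingness before
normalization; imputation runs last so the normalized distributions feed the
neighbour search.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GroupDesign

logger = logging.getLogger("mirlink.preprocess")

__all__ = [
    "collapse_replicates",
    "filter_mirna",
    "filter_mrna",
    "mask_outliers",
    "quantile_normalize",
    "knn_impute",
    "preprocess_matrix",
]


def collapse_replicates(m: ExpressionMatrix, design: GroupDesign) -> ExpressionMatrix:
    """Average technical replicate columns into one column per physical sample.

    The mean is taken over non-missing replicate values; an entry is missing
    only if it is missing in every replicate.
    """
    for col in m.sample_ids:
        if design.physical_of(col) not in design.group.index:
            raise KeyError(f"column {col!r} maps to unknown physical sample")
    cols = {}
    for phys in design.sample_ids:
        members = design.columns_of(phys, m.sample_ids)
        if not members:
            raise KeyError(f"no columns found for physical sample {phys!r}")
        cols[phys] = m.data[members].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols)[design.sample_ids]
    logger.info("collapsed %d columns into %d physical samples", m.n_samples, out.shape[1])
    return ExpressionMatrix(out, kind=m.kind)


def filter_mirna(
    m: ExpressionMatrix,
    design: GroupDesign,
    present_frac: float = 0.30,
    missing_frac: float = 0.40,
    filter_mode: str = "both",
) -> ExpressionMatrix:
    """Presence and missingness filters for the miRNA layer.

    A miRNA is dropped when its non-absent fraction falls below
    ``present_frac`` in *both* groups (``filter_mode="both"``, the default
    reading) or in *either* group (``filter_mode="either"``); survivors with
    an overall missing fraction strictly greater than ``missing_frac`` are
    then dropped.  Feature order is preserved.
    """
    if filter_mode not in ("both", "either"):
        raise ValueError("filter_mode must be 'both' or 'either'")
    obs = m.data.notna()
    case_cols = [s for s in m.sample_ids if s in design.case_ids]
    ctrl_cols = [s for s in m.sample_ids if s in design.control_ids]
    case_frac = obs[case_cols].mean(axis=1)
    ctrl_frac = obs[ctrl_cols].mean(axis=1)
    low_case = case_frac < present_frac
    low_ctrl = ctrl_frac < present_frac
    drop_presence = (low_case & low_ctrl) if filter_mode == "both" else (low_case | low_ctrl)
    kept = m.data.loc[~drop_presence]
    overall_missing = kept.isna().mean(axis=1)
    drop_missing = overall_missing > missing_frac
    out = kept.loc[~drop_missing]
    logger.info(
        "miRNA filter: dropped %d by presence (<%.0f%% in %s groups), %d by missingness (>%.0f%%)",
        int(drop_presence.sum()), 100 * present_frac, filter_mode,
        int(drop_missing.sum()), 100 * missing_frac,
    )
    return ExpressionMatrix(out.copy(), kind=m.kind)


def filter_mrna(m: ExpressionMatrix, missing_frac: float = 0.50) -> ExpressionMatrix:
    """Drop mRNAs whose missing fraction is ``missing_frac`` *or more*."""
    frac = m.data.isna().mean(axis=1)
    drop = frac >= missing_frac
    logger.info("mRNA filter: dropped %d of %d (missing >= %.0f%%)",
                int(drop.sum()), m.n_features, 100 * missing_frac)
    return ExpressionMatrix(m.data.loc[~drop].copy(), kind=m.kind)


def mask_outliers(m: ExpressionMatrix, k_sd: float = 3.0) -> ExpressionMatrix:
    """Mask entries farther than ``k_sd`` sample SDs from their feature mean.

    Mean and SD are computed once per feature over non-missing entries
    (single pass, no re-estimation after masking); the inequality is strict,
    so a value at exactly ``k_sd`` SDs is kept.  Features with fewer than 3
    observed values are left untouched and logged.
    """
    df = m.data.copy()
    n_obs = df.notna().sum(axis=1)
    skipped = df.index[n_obs < 3]
    if len(skipped):
        logger.warning("outlier masking skipped %d features with <3 observed values", len(skipped))
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    dev = df.sub(mean, axis=0).abs()
    mask = dev.gt(k_sd * sd, axis=0) & df.notna()
    mask.loc[skipped] = False
    n_masked = int(mask.to_numpy().sum())
    if n_masked:
        logger.info("masked %d outlier entries (> %g SD)", n_masked, k_sd)
    df = df.mask(mask)
    return ExpressionMatrix(df, kind=m.kind)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic between-array quantile normalization across sample columns.

    Each column's observed values are mapped to rank-averaged reference
    values.  The reference is built on a common quantile grid of length
    equal to the largest observed count, interpolating columns with missing
    entries onto that grid; tied values receive the mean of their tied
    ranks' reference values.  Missing entries remain missing.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    V = m.values.copy()
    counts = (~np.isnan(V)).sum(axis=0)
    big = int(counts.max())
    grid = np.linspace(0.0, 1.0, big) if big > 1 else np.array([0.0])
    curves = []
    for c in range(V.shape[1]):
        col = V[:, c]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        pos = np.linspace(0.0, 1.0, obs.size) if obs.size > 1 else np.array([0.5])
        curves.append(np.interp(grid, pos, obs))
    ref = np.mean(curves, axis=0)

    out = V.copy()
    for c in range(V.shape[1]):
        col = V[:, c]
        idx = np.flatnonzero(~np.isnan(col))
        if idx.size == 0:
            continue
        mc = idx.size
        pos = np.linspace(0.0, 1.0, mc) if mc > 1 else np.array([0.5])
        by_rank = np.interp(pos, grid, ref)  # reference value for each rank 0..mc-1
        ranks = rankdata(col[idx], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        vals = 0.5 * (by_rank[lo] + by_rank[hi])
        # ties: average the reference values of the full tied rank block
        s = pd.Series(col[idx])
        tied = s.duplicated(keep=False)
        if tied.any():
            order = np.argsort(col[idx], kind="mergesort")
            sorted_vals = col[idx][order]
            block_vals = by_rank.copy()
            df_blocks = pd.Series(block_vals).groupby(pd.Series(sorted_vals)).transform("mean")
            assigned = np.empty(mc)
            assigned[order] = df_blocks.to_numpy()
            vals = assigned
        out[idx, c] = vals
    return ExpressionMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids),
                            kind=m.kind)


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries from the k nearest features.

    Distance between two features is the root-mean-square difference over
    their jointly observed samples.  A missing entry is replaced by the
    unweighted mean of the values, at that sample, of the k nearest features
    observed there; entries with fewer than k usable neighbours fall back to
    the feature's own observed mean.  The returned matrix is complete.
    """
    V = m.values.copy()
    obs = ~np.isnan(V)
    if (~obs).sum() == 0:
        return ExpressionMatrix(m.data.copy(), kind=m.kind)
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("cannot impute a feature with zero observed values")

    A = np.where(obs, V, 0.0)
    W = obs.astype(float)
    # pairwise sums of squared differences over jointly observed samples
    s1 = (A ** 2) @ W.T
    cross = A @ A.T
    cnt = W @ W.T
    sq = s1 - 2.0 * cross + s1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / cnt)
    d[cnt == 0] = np.inf
    np.fill_diagonal(d, np.inf)

    own_mean = np.nanmean(V, axis=1)
    missing_rows = np.flatnonzero((~obs).any(axis=1))
    for i in missing_rows:
        order = np.argsort(d[i], kind="stable")
        order = order[np.isfinite(d[i][order])]
        for s in np.flatnonzero(~obs[i]):
            usable = order[obs[order, s]][:k]
            if usable.size < k:
                V[i, s] = own_mean[i]
            else:
                V[i, s] = V[usable, s].mean()
    logger.info("imputed %d missing entries (k=%d)", int((~obs).sum()), k)
    return ExpressionMatrix(pd.DataFrame(V, index=m.feature_ids, columns=m.sample_ids),
                            kind=m.kind)


def preprocess_matrix(
    m: ExpressionMatrix,
    design: GroupDesign,
    present_frac: float = 0.30,
    mirna_missing_frac: float = 0.40,
    mrna_missing_frac: float = 0.50,
    k_sd: float = 3.0,
    knn_k: int = 10,
    filter_mode: str = "both",
) -> ExpressionMatrix:
    """Run the full fixed-order preprocessing chain for one layer."""
    out = collapse_replicates(m, design)
    if m.kind == "miRNA":
        out = filter_mirna(out, design, present_frac, mirna_missing_frac, filter_mode)
    else:
        out = filter_mrna(out, mrna_missing_frac)
    out = mask_outliers(out, k_sd)
    out = quantile_normalize(out)
    out = knn_impute(out, knn_k)
    return out
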