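"""Co-abundance module detection on the intensity matrix.

Weighted correlation network analysis: postmortem-interval residualization,
iterative low-rank SVD imputation of missing cells, per-proteoform z-scaling,
soft-thresholded correlation adjacency, topological overlap, average-linkage
clustering of the TOM dissimilarity with a static tree cut, eigengene-based
module merging at a correlation-distance threshold, and module-trait
correlation with BH adjustment.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .stats import bh_adjust
from .types import NetworkConfig, QuantMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = 0


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------


def svd_impute(
    X: np.ndarray, rank: int = 5, tol: float = 1e-5, max_iter: int = 100
) -> np.ndarray:
    """Iterative rank-k SVD imputation of missing cells.

    Missing entries start at the row means; each iteration replaces them by
    the rank-k reconstruction until the relative change of the imputed values
    falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if rank >= min(X.shape):
        raise ValueError("impute rank must be below both matrix dimensions")
    miss = np.isnan(X)
    if not miss.any():
        return X.copy()
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    row_means = np.where(np.isnan(row_means), 0.0, row_means)
    filled[miss] = np.broadcast_to(row_means[:, None], X.shape)[miss]
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new_vals = recon[miss]
        old_vals = filled[miss]
        denom = max(np.linalg.norm(old_vals), 1e-12)
        change = np.linalg.norm(new_vals - old_vals) / denom
        filled[miss] = new_vals
        if change < tol:
            break
    return filled


def preprocess_for_network(
    qm: QuantMatrix, config: Optional[NetworkConfig] = None
) -> pd.DataFrame:
    """Filter, residualize PMI, impute and z-scale the intensity matrix.

    Rows observed in fewer than ``min_samples_observed`` samples are dropped;
    the postmortem-interval effect is regressed out of each row (on observed
    cells); remaining missing cells are SVD-imputed; rows are centred and
    scaled to unit SD so distances reflect correlation.
    """
    config = config or NetworkConfig()
    values = qm.values
    keep = values.notna().sum(axis=1) >= config.min_samples_observed
    values = values.loc[keep]
    if values.empty:
        raise ValueError("no proteoforms satisfy the completeness filter")
    pmi = qm.samples.loc[values.columns, "pmi_hours"].to_numpy(dtype=float)
    X = values.to_numpy(dtype=float).copy()
    design = np.column_stack([np.ones(len(pmi)), pmi])
    for g in range(X.shape[0]):
        mask = np.isfinite(X[g])
        if mask.sum() >= 3 and np.std(pmi[mask]) > 0:
            beta, *_ = np.linalg.lstsq(design[mask], X[g, mask], rcond=None)
            X[g, mask] = X[g, mask] - design[mask] @ beta
    if np.isnan(X).any():
        X = svd_impute(X, rank=min(config.impute_rank, min(X.shape) - 1))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    return pd.DataFrame(Z, index=values.index, columns=values.columns)


# --------------------------------------------------------------------------
# network construction and module detection
# --------------------------------------------------------------------------


def adjacency_matrix(z: np.ndarray, power: int = 6, sign: str = "unsigned") -> np.ndarray:
    corr = np.corrcoef(z)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    if sign == "unsigned":
        a = np.abs(corr) ** power
    else:
        a = ((1.0 + corr) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengenes(z: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First singular direction of each module in sample space, unit variance,
    sign-oriented so the mean member correlation is positive. Singleton
    modules use the member's own z-scores."""
    eigengenes = {}
    for mod in sorted(set(assignment) - {UNASSIGNED}):
        members = assignment.index[assignment == mod]
        M = z.loc[members].to_numpy(dtype=float)
        if M.shape[0] == 1:
            vec = M[0].copy()
        else:
            _, _, Vt = np.linalg.svd(M - M.mean(axis=1, keepdims=True),
                                     full_matrices=False)
            vec = Vt[0]
        sd = vec.std(ddof=1)
        vec = vec / (sd if sd > 0 else 1.0)
        cors = [np.corrcoef(vec, row)[0, 1] for row in M]
        if np.nanmean(cors) < 0:
            vec = -vec
        eigengenes[mod] = vec
    return pd.DataFrame(eigengenes, index=z.columns)


def _merge_close_modules(
    z: pd.DataFrame, assignment: pd.Series, merge_height: float
) -> pd.Series:
    """Iteratively merge modules whose eigengene correlation distance is
    below the merge height (closest pair first)."""
    assignment = assignment.copy()
    while True:
        mods = sorted(set(assignment) - {UNASSIGNED})
        if len(mods) < 2:
            break
        me = module_eigengenes(z, assignment)
        corr = np.corrcoef(me.to_numpy().T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= merge_height:
            break
        keep, drop = sorted((mods[i], mods[j]))
        assignment[assignment == drop] = keep
    return assignment


def detect_modules(
    z: pd.DataFrame, config: Optional[NetworkConfig] = None
) -> pd.Series:
    """Detect co-abundance modules on a complete z-scored matrix.

    Adjacency |cor|^beta (unsigned default), topological overlap, average
    linkage on 1 - TOM, static cut at ``cut_height``, minimum-size filter,
    then eigengene-based merging at ``merge_height``. Proteoforms in clusters
    below the minimum size are labeled 0 (unassigned). Module ids are
    renumbered 1..m by decreasing size.
    """
    config = config or NetworkConfig()
    n = z.shape[0]
    if n < config.min_module_size:
        logger.warning("fewer proteoforms than min_module_size; all unassigned")
        return pd.Series(UNASSIGNED, index=z.index)
    a = adjacency_matrix(z.to_numpy(dtype=float), config.soft_power, config.sign)
    tom = topological_overlap(a)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(link, t=config.cut_height, criterion="distance")
    assignment = pd.Series(UNASSIGNED, index=z.index)
    next_id = 1
    for lab in np.unique(raw):
        members = z.index[raw == lab]
        if len(members) >= config.min_module_size:
            assignment[members] = next_id
            next_id += 1
    if (assignment != UNASSIGNED).any():
        assignment = _merge_close_modules(z, assignment, config.merge_height)
    # renumber by decreasing size for stable, readable labels
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    relabel = {old: i + 1 for i, old in enumerate(sizes.index)}
    return assignment.map(lambda m: relabel.get(m, UNASSIGNED))


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    cohort: pd.DataFrame,
    traits: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Two-sided p-values from the t transform of r; BH adjustment across the
    module x trait family. Constant traits are recorded with NaN correlation.
    """
    meta = cohort.loc[eigengenes.index]
    rows = []
    for mod in eigengenes.columns:
        eg = eigengenes[mod].to_numpy(dtype=float)
        for trait in traits:
            tv = meta[trait].to_numpy(dtype=float)
            if np.nanstd(tv) == 0:
                rows.append(dict(module=mod, trait=trait, r=np.nan, p=np.nan,
                                 reason="constant_trait"))
                continue
            r, p = sps.pearsonr(eg, tv)
            rows.append(dict(module=mod, trait=trait, r=float(r), p=float(p),
                             reason=""))
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def format_module_trait_table(corr: pd.DataFrame) -> pd.DataFrame:
    """Module x trait table of 'r (p_adj)' strings, heatmap-style."""
    def fmt(row):
        if not np.isfinite(row["r"]):
            return ""
        return f"{row['r']:.2f} ({row['p_adj']:.2g})"

    corr = corr.copy()
    corr["cell"] = corr.apply(fmt, axis=1)
    return corr.pivot(index="module", columns="trait", values="cell")
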