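"""Batch-effect detection, parametric empirical-Bayes batch correction and
replicate dispersion reporting.

The correction follows the parametric location/scale empirical-Bayes scheme
(normal prior on batch means, inverse-gamma prior on batch variances, both
fitted by moments, posteriors solved iteratively). Missing cells are excluded
from estimation and corrected only where observed; after adjustment every row
is re-centred to its original batch-size-weighted grand mean so intercept-only
designs preserve row means exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class BatchReport:
    """One-way batch ANOVA on the leading principal components."""

    pc_f: list
    pc_p: list
    variance_explained: list
    imputed_for_pca: bool

    def to_dict(self) -> dict:
        return {
            "pc_f": self.pc_f,
            "pc_p": self.pc_p,
            "variance_explained": self.variance_explained,
            "imputed_for_pca": self.imputed_for_pca,
        }


def detect_batch_effect(qm: QuantMatrix, n_pcs: int = 5) -> BatchReport:
    """Test whether processing batch separates the top principal components.

    The (row-mean-imputed when incomplete) matrix is decomposed by SVD and
    each of the top ``n_pcs`` sample-space component scores is tested against
    batch by one-way ANOVA. Degenerate scores (no within- or between-group
    variance) report p = 1.
    """
    X = qm.values.to_numpy(dtype=float)
    batch = qm.samples.loc[qm.values.columns, "batch"].to_numpy()
    if len(np.unique(batch)) < 2:
        logger.warning("single batch: no batch-effect test performed")
        return BatchReport([], [], [], False)
    imputed = bool(np.isnan(X).any())
    if imputed:
        row_means = np.nanmean(X, axis=1)
        row_means = np.where(np.isnan(row_means), 0.0, row_means)
        X = np.where(np.isnan(X), row_means[:, None], X)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, vt.shape[0])
    var_exp = (s**2 / max((s**2).sum(), 1e-300))[:n_pcs]
    fs, ps = [], []
    for k in range(n_pcs):
        scores = vt[k]
        groups = [scores[batch == b] for b in np.unique(batch)]
        degenerate = s[k] ** 2 <= 1e-12 * max(1.0, float(s[0] ** 2))
        if degenerate or any(len(g) < 2 for g in groups) or np.allclose(
            scores, scores[0]
        ):
            fs.append(np.nan)
            ps.append(1.0)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*groups)
        if not np.isfinite(f):
            f, p = np.nan, 1.0
        fs.append(float(f))
        ps.append(float(p))
    return BatchReport(fs, ps, [float(v) for v in var_exp], imputed)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a_prior, b_prior, tol=1e-4, maxit=200):
    """Iterative EB posterior for batch location (gamma*) and scale (delta2*)."""
    n = np.sum(~np.isnan(z_batch), axis=1).astype(float)
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(maxit):
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (t2 * n * g_hat + d_new * g_bar) / (t2 * n + d_new)
        resid2 = np.nansum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * resid2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        if change < tol:
            break
    return g_new, d_new


def combat_correct(
    qm: QuantMatrix,
    covariates: Optional[Sequence[str]] = None,
) -> QuantMatrix:
    """Parametric empirical-Bayes batch correction of the intensity matrix.

    Per row the model ``y = alpha + X_cov beta + batch + noise`` is fitted by
    least squares on observed cells; data are standardized, batch-wise
    location/scale estimates are shrunk toward moment-fitted batch-level
    priors, adjusted, de-standardized and re-centred. Covariate effects
    (columns of the sample table named in ``covariates``) are preserved.
    """
    Y = qm.values.to_numpy(dtype=float).copy()
    samples = qm.values.columns
    batch = qm.samples.loc[samples, "batch"].to_numpy()
    ubatch = np.unique(batch)
    if len(ubatch) == 1:
        return QuantMatrix(qm.values.copy(), qm.samples, qm.proteoforms, qm.mode)
    sizes = {b: int((batch == b).sum()) for b in ubatch}
    for b, n in sizes.items():
        if n < 2:
            raise ValueError(f"batch {b} has a single sample; cannot correct")

    G, N = Y.shape
    B = np.stack([(batch == b).astype(float) for b in ubatch], axis=1)  # N x nb
    C = (
        qm.samples.loc[samples, list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((N, 0))
    )
    X = np.hstack([B, C])
    nb = len(ubatch)
    obs = ~np.isnan(Y)

    grand = np.zeros(G)
    cov_fit = np.zeros((G, N))
    sigma2 = np.zeros(G)
    frac = np.array([sizes[b] for b in ubatch], dtype=float)
    frac /= frac.sum()
    for g in range(G):
        m = obs[g]
        Xg, yg = X[m], Y[g, m]
        beta, *_ = np.linalg.lstsq(Xg, yg, rcond=None)
        grand[g] = frac @ beta[:nb]
        if C.shape[1]:
            cov_fit[g] = C @ beta[nb:]
        resid = yg - Xg @ beta
        sigma2[g] = np.sum(resid**2) / max(m.sum(), 1)
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))

    Z = (Y - grand[:, None] - cov_fit) / sigma[:, None]
    Z[~obs] = np.nan

    adj = Z.copy()
    for bi, b in enumerate(ubatch):
        cols = batch == b
        Zb = Z[:, cols]
        with np.errstate(invalid="ignore"):
            g_hat = np.nanmean(Zb, axis=1)
            n_obs_b = np.sum(~np.isnan(Zb), axis=1)
            d_hat = np.full(G, np.nan)
            enough = n_obs_b >= 2
            d_hat[enough] = np.nanvar(Zb[enough], axis=1, ddof=1)
        g_hat = np.where(np.isnan(g_hat), 0.0, g_hat)
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1)) if G > 1 else 1.0
        valid = np.isfinite(d_hat)
        m = float(np.nanmean(d_hat[valid])) if valid.any() else 1.0
        s2 = float(np.nanvar(d_hat[valid], ddof=1)) if valid.sum() > 1 else 0.0
        if s2 > 1e-12 and t2 > 1e-12:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            d_fill = np.where(valid, d_hat, m)
            g_star, d_star = _it_sol(Zb, g_hat, d_fill, g_bar, t2, a_prior, b_prior)
        else:
            # degenerate hyperpriors (identical or noiseless rows): no shrinkage
            g_star = g_hat
            d_star = np.where(valid & (d_hat > 1e-12), d_hat, max(m, 1.0))
        d_star = np.maximum(d_star, 1e-12)
        adj[:, cols] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adj * sigma[:, None] + grand[:, None] + cov_fit
    out[~obs] = np.nan
    # restore each row's original batch-size-weighted grand mean
    with np.errstate(invalid="ignore"):
        shift = np.nanmean(Y - out, axis=1)
    out += np.where(np.isnan(shift), 0.0, shift)[:, None]
    out[~obs] = np.nan
    values = pd.DataFrame(out, index=qm.values.index, columns=qm.values.columns)
    return QuantMatrix(values, qm.samples, qm.proteoforms, qm.mode)


def replicate_rsd(qm: QuantMatrix, replicate_groups: dict) -> float:
    """Median percent relative SD over replicate groups of columns.

    ``replicate_groups`` maps a group name to >= 2 sample ids. Abundances are
    recovered on the linear scale from the log2 ratios; per proteoform per
    group RSD = sample SD / mean x 100. Returns the median over all
    (proteoform, group) cells with >= 2 observations and nonzero mean.
    """
    linear = np.power(2.0, qm.values)
    rsds = []
    for name, cols in replicate_groups.items():
        if len(cols) < 2:
            raise ValueError(f"replicate group {name} needs >= 2 columns")
        sub = linear[list(cols)].to_numpy(dtype=float)
        n_obs = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
        ok = (n_obs >= 2) & (mean > 0)
        rsds.append(100.0 * sd[ok] / mean[ok])
    pooled = np.concatenate(rsds) if rsds else np.array([])
    return float(np.median(pooled)) if len(pooled) else float("nan")
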