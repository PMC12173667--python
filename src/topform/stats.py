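"""Proteoform-trait association testing.

Intensity mode: per-proteoform ordinary least squares of the log2 ratios on
a trait plus covariates, with residual variances shrunk across proteoforms by
empirical Bayes (scaled-F moment fit of the prior df and prior variance, as
in moderated-t analysis) and two-sided p-values on the augmented degrees of
freedom. Count mode: per-proteoform quasi-Poisson generalized linear model
(log link, sample-total offset, batch and postmortem-interval covariates)
with a Wald t-test on the trait coefficient using the Pearson dispersion.
Within each (trait, mode) family raw p-values are Benjamini-Hochberg
adjusted.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats as sps

from .types import QuantMatrix, TRAIT_COLUMNS

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# --------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Moment-fit the scaled-F prior and return (d0, s0^2, posterior s~^2).

    Models s^2 ~ s0^2 F(df, d0); the prior df d0 and prior variance s0^2 are
    fitted by matching the mean and variance of log s^2 to the log-F
    distribution. When the observed log-variances show no excess spread the
    prior df is infinite and every variance collapses to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        pooled = float(np.nanmean(s2[ok])) if ok.any() else np.nan
        return np.inf, pooled, np.where(ok, s2, pooled)
    e = np.log(s2[ok]) - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
        post = np.where(df > 0, post, s02)
    return float(d0), s02, post


# --------------------------------------------------------------------------
# intensity (moderated linear model) associations
# --------------------------------------------------------------------------


def fit_intensity_associations(
    qm: QuantMatrix,
    traits: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("pmi_hours",),
    moderated: bool = True,
) -> pd.DataFrame:
    """Moderated linear-model association of log2 ratios with each trait."""
    if qm.mode != "intensity":
        raise ValueError("expected an intensity-mode matrix")
    traits = list(traits) if traits is not None else [
        t for t in TRAIT_COLUMNS if t in qm.samples.columns
    ]
    Y = qm.values.to_numpy(dtype=float)
    meta = qm.samples.loc[qm.values.columns]
    results = []
    for trait in traits:
        tvals = meta[trait].to_numpy(dtype=float)
        if np.nanstd(tvals) == 0:
            logger.warning("trait %s is constant; skipped", trait)
            continue
        X = np.column_stack(
            [np.ones(len(tvals)), tvals]
            + [meta[c].to_numpy(dtype=float) for c in covariates]
        )
        p = X.shape[1]
        n_min = p + 2
        est = np.full(Y.shape[0], np.nan)
        s2 = np.full(Y.shape[0], np.nan)
        dfs = np.zeros(Y.shape[0])
        cs = np.full(Y.shape[0], np.nan)
        ns = np.zeros(Y.shape[0], dtype=int)
        for g in range(Y.shape[0]):
            mask = np.isfinite(Y[g])
            n = int(mask.sum())
            ns[g] = n
            if n < n_min:
                continue
            Xg, yg = X[mask], Y[g, mask]
            xtx = Xg.T @ Xg
            try:
                xtx_inv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                continue
            beta = xtx_inv @ (Xg.T @ yg)
            resid = yg - Xg @ beta
            dfs[g] = n - p
            est[g] = beta[1]
            s2[g] = float(resid @ resid) / (n - p)
            cs[g] = xtx_inv[1, 1]
        valid = np.isfinite(est) & (dfs > 0)
        if moderated and valid.sum() >= 2:
            d0, _, post = squeeze_variances(s2[valid], dfs[valid])
            s2_use = np.full_like(s2, np.nan)
            s2_use[valid] = post
            df_total = np.where(np.isinf(d0), np.inf, dfs + d0)
        else:
            s2_use = s2
            df_total = dfs
        se = np.sqrt(s2_use * cs)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = est / se
        pvals = np.where(
            np.isfinite(tstat),
            2.0 * sps.t.sf(np.abs(tstat), np.where(np.isinf(df_total), 1e9, df_total)),
            np.nan,
        )
        res = pd.DataFrame(
            {
                "proteoform_id": qm.values.index,
                "trait": trait,
                "estimate": est,
                "se": se,
                "statistic": tstat,
                "p": pvals,
                "df": df_total,
                "n": ns,
                "mode": "intensity",
            }
        )
        results.append(res)
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame(
        columns=["proteoform_id", "trait", "estimate", "se", "statistic", "p",
                 "df", "n", "mode"]
    )
    return out


# --------------------------------------------------------------------------
# spectral-count (quasi-Poisson) associations
# --------------------------------------------------------------------------


def fit_count_associations(
    qm: QuantMatrix,
    traits: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("batch", "pmi_hours"),
    sample_totals: Optional[pd.Series] = None,
    use_offset: bool = True,
    fix_dispersion: Optional[float] = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Quasi-Poisson GLM association of spectral counts with each trait.

    The linear predictor is trait + batch indicators + covariates with an
    offset of log(total accepted PrSMs per sample); the dispersion is the
    Pearson chi-square over residual df, and inference is a Wald t-test on
    the trait coefficient. ``fix_dispersion=1`` reproduces plain Poisson
    Wald statistics.
    """
    if qm.mode != "counts":
        raise ValueError("expected a counts-mode matrix")
    traits = list(traits) if traits is not None else [
        t for t in TRAIT_COLUMNS if t in qm.samples.columns
    ]
    meta = qm.samples.loc[qm.values.columns]
    if sample_totals is None:
        sample_totals = qm.values.sum(axis=0)
    totals = sample_totals.loc[qm.values.columns].to_numpy(dtype=float)
    offset = np.log(np.maximum(totals, 1.0)) if use_offset else np.zeros(len(totals))

    cov_cols = []
    cov_names = []
    for c in covariates:
        vals = meta[c].to_numpy(dtype=float)
        if c == "batch":
            ub = np.unique(vals)
            for b in ub[1:]:
                cov_cols.append((vals == b).astype(float))
                cov_names.append(f"batch_{int(b)}")
        else:
            cov_cols.append(vals)
            cov_names.append(c)

    rows = []
    Y = qm.values.to_numpy(dtype=float)
    for trait in traits:
        tvals = meta[trait].to_numpy(dtype=float)
        if np.nanstd(tvals) == 0:
            for pid in qm.values.index:
                rows.append(
                    dict(proteoform_id=pid, trait=trait, estimate=np.nan, se=np.nan,
                         statistic=np.nan, p=np.nan, dispersion=np.nan, df=0, n=0,
                         mode="counts", reason="constant_trait")
                )
            continue
        X = np.column_stack([np.ones(len(tvals)), tvals] + cov_cols)
        df_resid = X.shape[0] - X.shape[1]
        for g, pid in enumerate(qm.values.index):
            y = Y[g]
            if y.sum() == 0:
                rows.append(
                    dict(proteoform_id=pid, trait=trait, estimate=np.nan, se=np.nan,
                         statistic=np.nan, p=np.nan, dispersion=np.nan, df=0,
                         n=len(y), mode="counts", reason="all_zero")
                )
                continue
            try:
                model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
                fit = model.fit(maxiter=max_iter, tol=1e-8)
                converged = getattr(fit, "converged", True)
            except Exception:
                converged = False
            if not converged or df_resid <= 0:
                rows.append(
                    dict(proteoform_id=pid, trait=trait, estimate=np.nan, se=np.nan,
                         statistic=np.nan, p=np.nan, dispersion=np.nan, df=df_resid,
                         n=len(y), mode="counts", reason="not_converged")
                )
                continue
            phi = (
                float(fix_dispersion)
                if fix_dispersion is not None
                else float(fit.pearson_chi2 / df_resid)
            )
            se = fit.bse[1] * np.sqrt(max(phi, 1e-12))
            tstat = fit.params[1] / se
            p = float(2.0 * sps.t.sf(abs(tstat), df_resid))
            rows.append(
                dict(proteoform_id=pid, trait=trait, estimate=float(fit.params[1]),
                     se=float(se), statistic=float(tstat), p=p, dispersion=phi,
                     df=df_resid, n=len(y), mode="counts", reason="")
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# multiple-testing adjustment
# --------------------------------------------------------------------------


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    po = p[ok]
    order = np.argsort(po, kind="stable")
    ranked = po[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def adjust_bh(
    results: pd.DataFrame, group_cols: Sequence[str] = ("trait", "mode")
) -> pd.DataFrame:
    """Add a BH-adjusted p column within each (trait, mode) family."""
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(list(group_cols)).groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def association_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Punchcard-style proteoform x trait significance table."""
    sig = results.dropna(subset=["p_adj"])
    table = sig.pivot_table(
        index="proteoform_id", columns="trait", values="p_adj", aggfunc="min"
    )
    return (table < alpha).astype(int)
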