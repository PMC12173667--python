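"""Cross-run alignment, proteoform clustering, match-between-runs and the
construction of the two quantification matrices.

Accepted identifications from different LC-MS runs are reconciled into
study-wide proteoforms by grouping matches of the same gene that agree in
monoisotopic mass (0.8 Da tolerance) and aligned elution time. Missing
intensities are then transferred from unidentified MS1 features
(match-between-runs), and two proteoform x sample matrices are built: log2
intensity ratios and spectral counts, each with the study's completeness
filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import AlignConfig, QuantMatrix, Warp

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# retention-time alignment
# --------------------------------------------------------------------------


def align_retention_times(
    accepted: pd.DataFrame, config: Optional[AlignConfig] = None
) -> dict:
    """Fit per-run monotone piecewise-linear RT warps onto a reference run.

    The run with the most accepted PrSMs is the reference. For every other
    run, proteoform strings identified in both runs serve as anchors (median
    RT per string per run); a locally weighted fit followed by an isotonic
    projection yields a non-decreasing map from the run's RTs to the
    reference scale. Runs sharing fewer than ``min_anchors`` identifications
    with the reference fall back to the identity warp.
    """
    config = config or AlignConfig()
    counts = accepted.groupby("sample_id").size()
    reference_run = counts.idxmax()
    med = (
        accepted.groupby(["sample_id", "proteoform"])["rt_min"]
        .median()
        .reset_index()
    )
    ref = med[med["sample_id"] == reference_run].set_index("proteoform")["rt_min"]
    warps: dict = {}
    for run in counts.index:
        if run == reference_run:
            warps[run] = Warp(x=np.array([]), y=np.array([]), identity=True)
            continue
        mine = med[med["sample_id"] == run].set_index("proteoform")["rt_min"]
        shared = mine.index.intersection(ref.index)
        if len(shared) < config.min_anchors:
            logger.warning(
                "run %s shares only %d anchors with reference %s; identity warp",
                run, len(shared), reference_run,
            )
            warps[run] = Warp(x=np.array([]), y=np.array([]), identity=True)
            continue
        x = mine.loc[shared].to_numpy(dtype=float)
        y = ref.loc[shared].to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        smooth = lowess(y, x, frac=min(1.0, max(0.3, 20 / len(x))), return_sorted=False)
        iso = IsotonicRegression(increasing=True).fit_transform(x, smooth)
        ux, idx = np.unique(x, return_index=True)
        warps[run] = Warp(x=ux, y=np.asarray(iso)[idx])
    return warps


def apply_warps(df: pd.DataFrame, warps: dict, rt_col: str = "rt_min") -> pd.DataFrame:
    """Return a copy with an ``rt_aligned`` column on the reference scale."""
    out = df.copy()
    aligned = np.empty(len(out))
    for run, grp in out.groupby("sample_id"):
        warp = warps.get(run, Warp(x=np.array([]), y=np.array([]), identity=True))
        aligned[out.index.get_indexer(grp.index)] = warp(grp[rt_col].to_numpy())
    out["rt_aligned"] = aligned
    return out


# --------------------------------------------------------------------------
# proteoform clustering
# --------------------------------------------------------------------------


def cluster_proteoforms(
    accepted: pd.DataFrame, config: Optional[AlignConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage grouping of accepted PrSMs into study-wide proteoforms.

    Two observations of the same gene link when their masses differ by at
    most ``mass_tol_da`` and their aligned RTs by at most ``rt_window_min``;
    connected components become catalog entries. Repeated spectra of the same
    proteoform string within one run are first collapsed to a single
    representative point (median mass/RT, best E-value) — repeat acquisitions
    of one eluting species carry no extra clustering information. The
    representative mass and RT of a cluster are member medians; when member
    proteoform strings conflict, the string (and coordinates) of the
    lowest-E-value member are kept. The partition is invariant to row order.

    Returns (catalog, membership) where membership is ``accepted`` plus a
    ``proteoform_id`` column.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    config = config or AlignConfig()
    if "rt_aligned" not in accepted.columns:
        accepted = accepted.copy()
        accepted["rt_aligned"] = accepted["rt_min"]
    df = accepted.reset_index(drop=True)

    reps = (
        df.groupby(["gene", "proteoform", "sample_id"], sort=True)
        .agg(
            mass_da=("mass_da", "median"),
            rt_aligned=("rt_aligned", "median"),
            evalue=("evalue", "min"),
        )
        .reset_index()
    )
    reps["cluster"] = -1

    next_label = 0
    # canonical gene order keeps ids deterministic under row permutation
    for gene, sub in reps.groupby("gene", sort=True):
        m = len(sub)
        mass = sub["mass_da"].to_numpy()
        rt = sub["rt_aligned"].to_numpy()
        order = np.lexsort((rt, mass))
        mass_s, rt_s = mass[order], rt[order]
        if m <= 4000:
            adj = (
                np.abs(mass_s[:, None] - mass_s[None, :]) <= config.mass_tol_da
            ) & (np.abs(rt_s[:, None] - rt_s[None, :]) <= config.rt_window_min)
            _, comp = connected_components(csr_matrix(adj), directed=False)
        else:  # windowed sweep for very large genes
            rows, cols = [], []
            j_hi = np.searchsorted(mass_s, mass_s + config.mass_tol_da, side="right")
            for i in range(m):
                js = np.arange(i + 1, j_hi[i])
                js = js[np.abs(rt_s[js] - rt_s[i]) <= config.rt_window_min]
                rows.extend([i] * len(js))
                cols.extend(js)
            adj = csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(m, m)
            )
            _, comp = connected_components(adj, directed=False)
        # relabel components deterministically by their minimum member mass
        comp_min_mass = {}
        for c, mval in zip(comp, mass_s):
            comp_min_mass[c] = min(comp_min_mass.get(c, np.inf), mval)
        comp_rank = {
            c: next_label + r
            for r, c in enumerate(
                sorted(comp_min_mass, key=lambda c: comp_min_mass[c])
            )
        }
        labels_sorted = np.array([comp_rank[c] for c in comp])
        labels = np.empty(m, dtype=int)
        labels[order] = labels_sorted
        reps.loc[sub.index, "cluster"] = labels
        next_label += len(comp_rank)

    key = ["gene", "proteoform", "sample_id"]
    membership = df.merge(
        reps[key + ["cluster"]], on=key, how="left", sort=False
    ).rename(columns={"cluster": "proteoform_id"})

    cluster_rows = []
    for pid, sub_m in membership.groupby("proteoform_id", sort=True):
        best = sub_m.loc[sub_m["evalue"].idxmin()]
        cluster_rows.append(
            {
                "proteoform_id": int(pid),
                "gene": best["gene"],
                "accession": best["accession"],
                "tier": best["tier"],
                "proteoform": best["proteoform"],
                "start": int(best["start"]),
                "end": int(best["end"]),
                "mass_da": float(np.median(sub_m["mass_da"])),
                "rt_aligned": float(np.median(sub_m["rt_aligned"])),
                "n_prsms": int(len(sub_m)),
            }
        )
    catalog = pd.DataFrame(cluster_rows).set_index("proteoform_id", drop=False)
    return catalog, membership


# --------------------------------------------------------------------------
# match-between-runs
# --------------------------------------------------------------------------


def match_between_runs(
    catalog: pd.DataFrame,
    membership: pd.DataFrame,
    features: pd.DataFrame,
    warps: dict,
    config: Optional[AlignConfig] = None,
) -> pd.DataFrame:
    """Transfer MS1 feature intensities into unidentified (proteoform, run) cells.

    For each cell lacking an identification, the closest feature of that run
    within the mass tolerance and RT window (ranked by |dmass| then |dRT|)
    supplies the intensity; such cells are flagged ``transferred``. Identified
    cells are never overwritten. Returns a long table
    (proteoform_id, sample_id, intensity, transferred).
    """
    config = config or AlignConfig()
    ident = (
        membership.groupby(["proteoform_id", "sample_id"])["intensity"]
        .max()
        .reset_index()
    )
    ident["transferred"] = False
    if not config.mbr_enabled:
        return ident
    feats = apply_warps(features, warps)
    rows = []
    have = set(zip(ident["proteoform_id"], ident["sample_id"]))
    identified_missing = ident[ident["intensity"].isna()]
    runs = feats.groupby("sample_id")
    run_cache = {
        run: (grp["mass_da"].to_numpy(), grp["rt_aligned"].to_numpy(),
              grp["intensity"].to_numpy())
        for run, grp in runs
    }
    all_runs = sorted(run_cache)
    for pid, pmassv, prt in zip(
        catalog["proteoform_id"], catalog["mass_da"], catalog["rt_aligned"]
    ):
        for run in all_runs:
            key = (pid, run)
            if key in have:
                continue
            fmass, frt, fint = run_cache[run]
            dm = np.abs(fmass - pmassv)
            drt = np.abs(frt - prt)
            cand = np.flatnonzero((dm <= config.mass_tol_da) & (drt <= config.rt_window_min))
            if len(cand) == 0:
                continue
            best = cand[np.lexsort((drt[cand], dm[cand]))[0]]
            rows.append(
                {
                    "proteoform_id": pid,
                    "sample_id": run,
                    "intensity": fint[best],
                    "transferred": True,
                }
            )
    # identified cells whose own intensity is absent can also be rescued
    for _, r in identified_missing.iterrows():
        pid, run = r["proteoform_id"], r["sample_id"]
        if run not in run_cache or pid not in catalog.index:
            continue
        fmass, frt, fint = run_cache[run]
        pmassv = catalog.loc[pid, "mass_da"]
        prt = catalog.loc[pid, "rt_aligned"]
        dm = np.abs(fmass - pmassv)
        drt = np.abs(frt - prt)
        cand = np.flatnonzero((dm <= config.mass_tol_da) & (drt <= config.rt_window_min))
        if len(cand) == 0:
            continue
        best = cand[np.lexsort((drt[cand], dm[cand]))[0]]
        ident.loc[
            (ident["proteoform_id"] == pid) & (ident["sample_id"] == run), "intensity"
        ] = fint[best]
    out = pd.concat([ident, pd.DataFrame(rows)], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# quantification matrices
# --------------------------------------------------------------------------


@dataclass
class CompletenessConfig:
    """Completeness filters, expressed so scaled-down studies keep the intent.

    The intensity matrix keeps proteoforms observed in at least
    ``ceil(intensity_min_frac * n_samples)`` samples (50/103 in the study);
    the counts matrix keeps proteoforms present in >= ``counts_min_samples``
    samples with >= ``counts_min_batches`` batches each contributing
    >= ``counts_min_per_batch`` total counts.
    """

    intensity_min_frac: float = 50 / 103
    counts_min_samples: int = 6
    counts_min_batches: int = 3
    counts_min_per_batch: int = 2


def build_quant_matrices(
    catalog: pd.DataFrame,
    membership: pd.DataFrame,
    intensities: pd.DataFrame,
    cohort: pd.DataFrame,
    config: Optional[CompletenessConfig] = None,
) -> tuple[QuantMatrix, QuantMatrix]:
    """Build the intensity (log2-ratio) and spectral-count matrices.

    Intensities are log2-transformed relative to each proteoform's
    across-sample median (log2 ratios). Spectral counts are the number of
    accepted PrSMs per proteoform per sample, with absent cells as zeros.
    """
    config = config or CompletenessConfig()
    samples = list(cohort["sample_id"])
    unknown = set(membership["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(f"samples missing from cohort: {sorted(unknown)}")
    sample_meta = cohort.reset_index(drop=True).set_index("sample_id", drop=False)

    wide = (
        intensities.pivot_table(
            index="proteoform_id", columns="sample_id", values="intensity",
            aggfunc="max",
        )
        .reindex(index=catalog.index, columns=samples)
    )
    log2 = np.log2(wide.where(wide > 0))
    ratios = log2.sub(log2.median(axis=1, skipna=True), axis=0)
    min_obs = int(np.ceil(config.intensity_min_frac * len(samples)))
    keep_i = ratios.notna().sum(axis=1) >= min_obs
    intensity_qm = QuantMatrix(
        values=ratios.loc[keep_i],
        samples=sample_meta,
        proteoforms=catalog.loc[keep_i],
        mode="intensity",
    )

    counts = (
        membership.groupby(["proteoform_id", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=catalog.index, columns=samples, fill_value=0)
        .astype(int)
    )
    batch_of = cohort.set_index("sample_id")["batch"]
    batch_totals = counts.T.groupby(batch_of).sum().T  # proteoform x batch
    present_samples = (counts > 0).sum(axis=1)
    good_batches = (batch_totals >= config.counts_min_per_batch).sum(axis=1)
    keep_c = (present_samples >= config.counts_min_samples) & (
        good_batches >= config.counts_min_batches
    )
    counts_qm = QuantMatrix(
        values=counts.loc[keep_c],
        samples=sample_meta,
        proteoforms=catalog.loc[keep_c],
        mode="counts",
    )
    return intensity_qm, counts_qm


def spectral_counts(membership: pd.DataFrame, samples) -> pd.DataFrame:
    """Unfiltered counts matrix (used for conservation checks and offsets)."""
    return (
        membership.groupby(["proteoform_id", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(samples), fill_value=0)
        .astype(int)
    )
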