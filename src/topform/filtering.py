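"""Identification filtering: pooling, tiered gene-level FDR control, the
multilevel FDR report and parsimonious accession inference.

The search engine's output is filtered in the study's order: an E-value
ceiling of 0.05, a requirement that a proteoform string be observed in at
least two samples, then a per-annotation-tier E-value threshold chosen so
the target-decoy estimate of the gene-level false discovery rate does not
exceed 1%, followed by greedy parsimonious protein inference.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import FdrPolicy, FdrReport, TIER_PRIORITY

logger = logging.getLogger(__name__)

_MOD_TOKEN = re.compile(r"\[[^\]]*\]")

EVALUE_CEILING = 0.05

LEVELS = ("prsm", "proteoform", "sequence", "accession", "gene")


def strip_modifications(proteoform: str) -> str:
    """Remove bracketed modification tokens, keeping the bare residue string."""
    return _MOD_TOKEN.sub("", proteoform).lstrip("-")


def pool_and_prefilter(
    prsm_tables,
    min_samples: int = 2,
    evalue_ceiling: float = EVALUE_CEILING,
) -> pd.DataFrame:
    """Pool PrSM tables and keep proteoforms seen in >= min_samples samples.

    The E-value ceiling is applied first (to targets and decoys alike), then
    records whose proteoform string occurs in fewer than ``min_samples``
    distinct samples are dropped.
    """
    if isinstance(prsm_tables, pd.DataFrame):
        prsm_tables = [prsm_tables]
    prsm_tables = list(prsm_tables)
    if not prsm_tables:
        raise ValueError("at least one PrSM table is required")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    pooled = pd.concat(prsm_tables, ignore_index=True)
    pooled = pooled[pooled["evalue"] <= evalue_ceiling]
    n_samples = pooled.groupby("proteoform")["sample_id"].transform("nunique")
    return pooled[n_samples >= min_samples].reset_index(drop=True)


@dataclass
class FilterResult:
    """Outcome of tiered gene-FDR thresholding."""

    accepted: pd.DataFrame  # accepted target PrSMs
    accepted_decoys: pd.DataFrame  # decoy PrSMs passing the same cutoffs
    cutoffs: dict  # tier -> E-value cutoff (None if tier rejected everything)
    tier_counts: dict = field(default_factory=dict)


def _tier_threshold(genes: pd.DataFrame, q: float):
    """Scan gene-score cutoffs; return (cutoff, accepted target genes, est FDR).

    ``genes`` has columns gene, is_decoy, score (minimum E-value). Targets are
    ranked before decoys at tied scores (optimistic tie-break). The largest
    cutoff whose conservative (D+1)/T estimate stays within q is selected.
    When the tier contains no decoy genes the scan is uninformative and the
    maximum gene score is accepted, reporting the 1/T floor.
    """
    genes = genes.sort_values(["score", "is_decoy"], kind="stable").reset_index(drop=True)
    t_cum = (~genes["is_decoy"]).cumsum().to_numpy()
    d_cum = genes["is_decoy"].cumsum().to_numpy()
    if d_cum[-1] == 0:
        cutoff = float(genes["score"].max())
        t = int(t_cum[-1])
        return cutoff, set(genes["gene"]), (1.0 / t if t else np.nan)
    est = (d_cum + 1) / np.maximum(t_cum, 1)
    ok = np.flatnonzero(est <= q)
    if len(ok) == 0:
        return None, set(), np.nan
    k = int(ok[-1])
    cutoff = float(genes["score"].iloc[k])
    head = genes.iloc[: k + 1]
    accepted = set(head.loc[~head["is_decoy"], "gene"])
    return cutoff, accepted, float(est[k])


def tier_gene_fdr_threshold(
    pooled: pd.DataFrame, policy: Optional[FdrPolicy] = None
) -> FilterResult:
    """Threshold E-values per annotation tier at <= q gene-level decoy FDR.

    Within each tier each gene is scored by its minimum E-value; the sorted
    distinct gene scores are scanned and the largest cutoff with estimated
    gene FDR (decoy genes + 1)/targets <= q is kept. All PrSMs of accepted
    target genes with E-value <= cutoff are accepted; decoys passing the
    cutoff are retained separately for reporting.
    """
    policy = policy or FdrPolicy()
    accepted_parts, decoy_parts = [], []
    cutoffs: dict = {}
    tier_counts: dict = {}
    for tier, sub in pooled.groupby("tier"):
        if (~sub["is_decoy"]).sum() == 0:
            logger.warning("tier %s has no target PrSMs; empty acceptance", tier)
            cutoffs[tier] = None
            continue
        genes = (
            sub.groupby(["gene", "is_decoy"])["evalue"]
            .min()
            .reset_index()
            .rename(columns={"evalue": "score"})
        )
        cutoff, accepted_genes, est = _tier_threshold(genes, policy.q)
        cutoffs[tier] = cutoff
        if cutoff is None:
            logger.warning("tier %s: no cutoff satisfies q=%.3g", tier, policy.q)
            tier_counts[tier] = {"targets": 0, "decoys": 0, "estimated_fdr": None}
            continue
        acc = sub[
            (~sub["is_decoy"])
            & sub["gene"].isin(accepted_genes)
            & (sub["evalue"] <= cutoff)
        ]
        dec = sub[sub["is_decoy"] & (sub["evalue"] <= cutoff)]
        accepted_parts.append(acc)
        decoy_parts.append(dec)
        tier_counts[tier] = {
            "targets": int(acc["gene"].nunique()),
            "decoys": int(dec["gene"].nunique()),
            "estimated_fdr": est,
        }
    accepted = (
        pd.concat(accepted_parts, ignore_index=True)
        if accepted_parts
        else pooled.iloc[0:0].copy()
    )
    decoys = (
        pd.concat(decoy_parts, ignore_index=True)
        if decoy_parts
        else pooled.iloc[0:0].copy()
    )
    return FilterResult(
        accepted=accepted, accepted_decoys=decoys, cutoffs=cutoffs, tier_counts=tier_counts
    )


def _level_keys(df: pd.DataFrame, level: str) -> pd.Series:
    if level == "prsm":
        return pd.Series(np.arange(len(df)), index=df.index)
    if level == "proteoform":
        return df["proteoform"]
    if level == "sequence":
        return df["proteoform"].map(strip_modifications)
    if level == "accession":
        return df["accession"]
    if level == "gene":
        return df["gene"]
    raise ValueError(f"unknown level {level!r}")


def multilevel_fdr_report(result: FilterResult) -> FdrReport:
    """Decoy-estimated FDR at the five reporting levels (plain D/T)."""
    achieved, counts = {}, {}
    for level in LEVELS:
        t = int(_level_keys(result.accepted, level).nunique())
        d = int(_level_keys(result.accepted_decoys, level).nunique())
        achieved[level] = (d / t) if t else 0.0
        counts[level] = {"targets": t, "decoys": d}
    return FdrReport(achieved=achieved, cutoffs=result.cutoffs, counts=counts)


def infer_parsimonious_accessions(
    accepted: pd.DataFrame,
    membership: Optional[Mapping[str, Iterable[str]]] = None,
    tiers: Optional[Mapping[str, str]] = None,
) -> dict:
    """Greedy minimal-set-cover assignment of proteoforms to accessions.

    ``membership`` maps each proteoform string to the accessions that can
    explain it (defaults to the accessions observed in the table). Repeatedly
    the accession explaining the most unassigned proteoforms is selected;
    ties break by annotation tier (canonical > isoform > tentative) then
    lexicographic accession. Returns proteoform -> representative accession.
    """
    if membership is None:
        membership = (
            accepted.groupby("proteoform")["accession"].agg(set).to_dict()
        )
    if tiers is None:
        tiers = accepted.groupby("accession")["tier"].first().to_dict()
    acc_to_pforms: dict = {}
    for pform, accs in membership.items():
        for acc in accs:
            acc_to_pforms.setdefault(acc, set()).add(pform)
    remaining = set(membership)
    assignment: dict = {}
    while remaining:
        best = min(
            acc_to_pforms,
            key=lambda a: (
                -len(acc_to_pforms[a] & remaining),
                TIER_PRIORITY.get(tiers.get(a, "tentative"), 3),
                a,
            ),
        )
        covered = acc_to_pforms[best] & remaining
        if not covered:
            break
        for pform in covered:
            assignment[pform] = best
        remaining -= covered
    return assignment
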