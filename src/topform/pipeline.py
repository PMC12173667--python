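"""End-to-end orchestration of the analysis stages.

Stages communicate only through plain-text files in the output directory, so
any stage can be re-run from its persisted inputs: simulate -> filter ->
quantify -> batch-correct -> associate -> modules -> annotate. A manifest
records the seed, parameter values and row counts per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annot, batch, filtering, network, quant, stats, synth
from . import io as tio
from .types import AlignConfig, FdrPolicy, NetworkConfig, TRAIT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study-stated values."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # simulate
    n_genes: int = 60
    n_samples: int = 103
    n_batches: int = 6
    # filter
    q: float = 0.01
    min_samples: int = 2
    evalue_ceiling: float = 0.05
    # quantify
    mass_tol_da: float = 0.8
    rt_window_min: float = 2.0
    mbr: bool = True
    intensity_min_frac: float = 50 / 103
    # associate
    alpha: float = 0.05
    covariates_intensity: tuple = ("pmi_hours",)
    covariates_counts: tuple = ("batch", "pmi_hours")
    # modules
    min_samples_observed_frac: float = 51 / 103
    soft_power: int = 6
    min_module_size: int = 5
    merge_height: float = 0.15

    def validate(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.n_samples < self.n_batches or self.n_batches < 1:
            raise ValueError("need n_samples >= n_batches >= 1")
        if self.mass_tol_da <= 0 or self.rt_window_min <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.merge_height < 1.0:
            raise ValueError("merge_height must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def stage_simulate(cfg: PipelineConfig, study_dir: str) -> synth.Study:
    reference = synth.make_reference_db(cfg.n_genes, seed=cfg.seed)
    cohort = synth.make_cohort(cfg.n_samples, cfg.n_batches, seed=cfg.seed + 1)
    study = synth.simulate_study(reference, cohort, seed=cfg.seed + 2)
    synth.write_study(study, study_dir)
    return study


def stage_filter(cfg: PipelineConfig, study: synth.Study, outdir: str):
    pooled = filtering.pool_and_prefilter(
        study.prsms, min_samples=cfg.min_samples, evalue_ceiling=cfg.evalue_ceiling
    )
    result = filtering.tier_gene_fdr_threshold(pooled, FdrPolicy(q=cfg.q))
    report = filtering.multilevel_fdr_report(result)
    assignment = filtering.infer_parsimonious_accessions(result.accepted)
    accepted = result.accepted.copy()
    accepted["rep_accession"] = accepted["proteoform"].map(assignment)
    tio.write_prsm_tsv(accepted, os.path.join(outdir, "accepted_prsms.tsv"))
    with open(os.path.join(outdir, "fdr_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    pd.Series(assignment, name="accession").rename_axis("proteoform").to_csv(
        os.path.join(outdir, "accession_map.tsv"), sep="\t"
    )
    return accepted, report


def stage_quantify(cfg: PipelineConfig, accepted, features, cohort, outdir: str):
    align_cfg = AlignConfig(
        mass_tol_da=cfg.mass_tol_da, rt_window_min=cfg.rt_window_min,
        mbr_enabled=cfg.mbr,
    )
    warps = quant.align_retention_times(accepted, align_cfg)
    aligned = quant.apply_warps(accepted, warps)
    catalog, membership = quant.cluster_proteoforms(aligned, align_cfg)
    intensities = quant.match_between_runs(
        catalog, membership, features, warps, align_cfg
    )
    comp = quant.CompletenessConfig(intensity_min_frac=cfg.intensity_min_frac)
    intensity_qm, counts_qm = quant.build_quant_matrices(
        catalog, membership, intensities, cohort, comp
    )
    catalog.to_csv(os.path.join(outdir, "catalog.tsv"), sep="\t", index=False)
    tio.write_quant_matrix(intensity_qm, outdir, "intensity")
    tio.write_quant_matrix(counts_qm, outdir, "counts")
    totals = quant.spectral_counts(membership, cohort["sample_id"]).sum(axis=0)
    totals.to_csv(os.path.join(outdir, "sample_totals.csv"))
    return catalog, membership, intensity_qm, counts_qm, totals


def stage_batch_correct(cfg: PipelineConfig, intensity_qm, outdir: str):
    report = batch.detect_batch_effect(intensity_qm)
    corrected = batch.combat_correct(intensity_qm)
    with open(os.path.join(outdir, "batch_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    tio.write_quant_matrix(corrected, outdir, "intensity_corrected")
    return corrected, report


def stage_associate(cfg: PipelineConfig, corrected, counts_qm, totals, outdir: str):
    res_i = stats.fit_intensity_associations(
        corrected, covariates=cfg.covariates_intensity
    )
    res_c = stats.fit_count_associations(
        counts_qm, covariates=cfg.covariates_counts, sample_totals=totals
    )
    results = stats.adjust_bh(pd.concat([res_i, res_c], ignore_index=True))
    results.to_csv(os.path.join(outdir, "associations.tsv"), sep="\t", index=False)
    punch = stats.association_summary(results, alpha=cfg.alpha)
    punch.to_csv(os.path.join(outdir, "association_punchcard.tsv"), sep="\t")
    return results


def stage_modules(cfg: PipelineConfig, corrected, cohort, outdir: str):
    net_cfg = NetworkConfig(
        min_samples_observed=int(
            np.ceil(cfg.min_samples_observed_frac * corrected.values.shape[1])
        ),
        soft_power=cfg.soft_power,
        min_module_size=cfg.min_module_size,
        merge_height=cfg.merge_height,
    )
    z = network.preprocess_for_network(corrected, net_cfg)
    assignment = network.detect_modules(z, net_cfg)
    eigengenes = network.module_eigengenes(z, assignment)
    traits = [t for t in TRAIT_COLUMNS if t in cohort.columns]
    corr = (
        network.module_trait_correlation(eigengenes, cohort, traits)
        if not eigengenes.empty
        else pd.DataFrame(columns=["module", "trait", "r", "p", "p_adj"])
    )
    assignment.rename("module").rename_axis("proteoform_id").to_csv(
        os.path.join(outdir, "module_membership.tsv"), sep="\t"
    )
    eigengenes.to_csv(os.path.join(outdir, "eigengenes.csv"))
    corr.to_csv(os.path.join(outdir, "module_trait_correlation.tsv"), sep="\t",
                index=False)
    if not corr.empty:
        network.format_module_trait_table(corr).to_csv(
            os.path.join(outdir, "module_trait_table.tsv"), sep="\t"
        )
    return z, assignment, eigengenes, corr


def stage_annotate(cfg: PipelineConfig, catalog, reference, assignment, outdir: str):
    ref_by_acc = {e.accession: e for e in reference if not e.is_decoy}
    tracks = {e.accession: e.plddt for e in reference if e.plddt is not None}
    catalog = _with_mods(catalog, ref_by_acc)
    sites = annot.catalog_cleavage_sites(catalog, ref_by_acc)
    ctx = annot.cleavage_structure_context(sites, tracks)
    ptm_table = annot.ptm_frequency_table(catalog)
    abeta = annot.abeta_map_table(catalog)
    vgf_entry = ref_by_acc.get(synth.VGF_ACCESSION)
    vgf_map = None
    if vgf_entry is not None:
        observed = [
            s.site
            for s in sites
            if s.accession == synth.VGF_ACCESSION
        ]
        table, coverage, novel = annot.dibasic_cleavage_map(
            vgf_entry, observed, vgf_entry.regions.get("known_sites")
        )
        table.to_csv(os.path.join(outdir, "vgf_cleavage_map.tsv"), sep="\t", index=False)
        vgf_map = {"dibasic_coverage": coverage, "novel_sites": novel}
    ptm_table.to_csv(os.path.join(outdir, "ptm_frequencies.tsv"), sep="\t", index=False)
    if not abeta.empty:
        abeta.to_csv(os.path.join(outdir, "abeta_map.tsv"), sep="\t", index=False)
    summary = {
        "cleavage_ks_p": ctx.ks_p,
        "cleavage_median_shift": ctx.median_shift,
        "frac_site_means_below_50": ctx.frac_below_50,
        "n_sites": ctx.n_sites_used,
        "vgf": vgf_map,
    }
    with open(os.path.join(outdir, "annotation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _with_mods(catalog: pd.DataFrame, ref_by_acc) -> pd.DataFrame:
    """Ensure the catalog carries a parseable mods column (derive from string)."""
    if "mods" in catalog.columns:
        return catalog
    out = catalog.copy()
    import re

    def mods_from_string(s):
        return ";".join(f"{m}@x" for m in re.findall(r"\[([^\]]+)\]", str(s)))

    out["mods"] = out["proteoform"].map(mods_from_string)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    cfg.validate()
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "parameters": dataclasses.asdict(cfg)}

    study_dir = os.path.join(outdir, "study")
    study = stage_simulate(cfg, study_dir)
    manifest["simulate"] = {
        "n_prsms": int(len(study.prsms)),
        "n_features": int(len(study.features)),
        "n_true_proteoforms": int(len(study.truth.catalog)),
    }

    accepted, report = stage_filter(cfg, study, outdir)
    manifest["filter"] = {
        "n_accepted_prsms": int(len(accepted)),
        "achieved_fdr": report.achieved,
    }

    catalog, membership, intensity_qm, counts_qm, totals = stage_quantify(
        cfg, accepted, study.features, study.cohort, outdir
    )
    manifest["quantify"] = {
        "n_catalog": int(len(catalog)),
        "intensity_rows": int(intensity_qm.values.shape[0]),
        "counts_rows": int(counts_qm.values.shape[0]),
    }

    corrected, breport = stage_batch_correct(cfg, intensity_qm, outdir)
    manifest["batch_correct"] = {"pc_p": breport.pc_p}

    results = stage_associate(cfg, corrected, counts_qm, totals, outdir)
    n_sig = int(
        ((results["p_adj"] < cfg.alpha) & results["p_adj"].notna()).sum()
    )
    manifest["associate"] = {"n_tests": int(len(results)), "n_significant": n_sig}

    z, assignment, eigengenes, corr = stage_modules(cfg, corrected, study.cohort, outdir)
    manifest["modules"] = {
        "n_modules": int((assignment[assignment != 0]).nunique()),
        "n_unassigned": int((assignment == 0).sum()),
    }

    summary = stage_annotate(cfg, catalog, study.reference, assignment, outdir)
    manifest["annotate"] = summary

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
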