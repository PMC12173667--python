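"""Study-level summary quantities.

Small, explicit computations used by the reporting layer: proteome coverage,
catalog density per protein, module sizing, cohort composition, and the
amyloid-beta coordinate anchor recovered from the labeling operation itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annot import abeta_label
from .filtering import pool_and_prefilter, tier_gene_fdr_threshold
from .types import FdrPolicy


def proteome_coverage_percent(n_proteins: int, proteome_size: int) -> float:
    """Identified proteins as a percentage of the reference proteome."""
    if proteome_size <= 0:
        raise ValueError("proteome_size must be positive")
    return 100.0 * n_proteins / proteome_size


def mean_module_size(n_proteoforms: int, n_modules: int) -> float:
    """Average number of proteoforms per co-abundance module."""
    if n_modules <= 0:
        raise ValueError("n_modules must be positive")
    return n_proteoforms / n_modules


def proteoforms_per_protein(n_proteoforms: int, n_proteins: int) -> float:
    """Average catalog depth: quantified proteoforms per parent protein."""
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    return n_proteoforms / n_proteins


def female_percent(cohort: pd.DataFrame) -> float:
    """Percentage of female participants in a cohort table."""
    return 100.0 * float(cohort["female"].mean())


def app_residue_of_abeta_position(position: int = 1) -> int:
    """APP residue index mapping to a given amyloid-beta position.

    Recovered by inverting the labeling operation: scan candidate APP start
    residues and return the one whose label carries the requested position.
    """
    for start in range(600, 800):
        try:
            lab = abeta_label(start, 713)
        except ValueError:
            continue
        if lab.x == position:
            return start
    raise ValueError(f"no APP residue maps to amyloid-beta position {position}")


def true_gene_fdr(study, q: float = 0.01) -> float:
    """True gene-level FDR of the full filtering procedure against truth.

    Runs the deployed identification filter (E-value ceiling, two-sample
    prefilter, per-tier gene-FDR thresholding) on a simulated study and
    scores accepted target genes against the generator's presence labels.
    """
    pooled = pool_and_prefilter(study.prsms)
    result = tier_gene_fdr_threshold(pooled, FdrPolicy(q=q))
    genes = set(result.accepted["gene"])
    if not genes:
        return 0.0
    false = sum(1 for g in genes if not study.truth.gene_present.get(g, False))
    return false / len(genes)
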