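"""Shared domain containers for the top-down proteoform analysis pipeline.

Tabular data (PrSM tables, feature tables, quantification matrices) travel as
pandas objects with documented column schemas; small structured values are
dataclasses. Coordinates are 1-based inclusive residue positions on the
reference protein sequence throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column schema of the PrSM (proteoform-spectrum match) table dialect.
PRSM_COLUMNS = [
    "sample_id",
    "scan",
    "accession",
    "tier",
    "gene",
    "proteoform",
    "start",
    "end",
    "mass_da",
    "rt_min",
    "evalue",
    "intensity",
    "is_decoy",
]

#: Column schema of the per-run MS1 feature tables used for match-between-runs.
FEATURE_COLUMNS = ["sample_id", "mass_da", "rt_min", "intensity"]

TIERS = ("canonical", "isoform", "tentative")
TIER_PRIORITY = {"canonical": 0, "isoform": 1, "tentative": 2}

DECOY_PREFIX = "DECOY_"

#: Clinicopathological variables tested for association, in display order.
TRAIT_COLUMNS = [
    "tangles",
    "amyloid",
    "lewy_body",
    "hip_sclerosis",
    "infarcts",
    "caa",
    "arteriolosclerosis",
    "apoe4",
    "global_cognition",
    "decline_slope",
    "decline_slope_adj",
]


@dataclass
class ReferenceEntry:
    """One protein database entry (target or scrambled decoy).

    ``plddt`` is the per-residue structural-confidence track (0-100); values
    below 50 indicate predicted disorder. ``regions`` carries optional named
    annotations such as ``abeta`` (start, end), ``linkers`` (list of
    (start, end) low-confidence segments) or ``known_sites`` (list of
    previously described cleavage-bond indices).
    """

    accession: str
    gene: str
    tier: str
    sequence: str
    plddt: Optional[np.ndarray] = None
    is_decoy: bool = False
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(AMINO_ACIDS):
            raise ValueError(f"{self.accession}: sequence must be non-empty over {AMINO_ACIDS}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if len(self.plddt) != len(self.sequence):
                raise ValueError(f"{self.accession}: pLDDT length != sequence length")


@dataclass
class FdrPolicy:
    """False-discovery-rate control policy for identification filtering."""

    level: str = "gene"
    q: float = 0.01
    per_tier: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.level not in ("prsm", "proteoform", "sequence", "accession", "gene"):
            raise ValueError(f"unknown FDR level {self.level!r}")


@dataclass
class FdrReport:
    """Decoy-estimated FDR achieved at the five reporting levels (fractions)."""

    achieved: dict  # level -> plain D/T estimate
    cutoffs: dict  # tier -> accepted E-value cutoff (None when tier empty)
    counts: dict  # level -> {"targets": int, "decoys": int}

    def to_dict(self) -> dict:
        return {
            "achieved_fdr": self.achieved,
            "evalue_cutoffs": self.cutoffs,
            "counts": self.counts,
        }


@dataclass
class AlignConfig:
    """Cross-run alignment / clustering / match-between-runs settings."""

    mass_tol_da: float = 0.8
    rt_window_min: float = 2.0
    mbr_enabled: bool = True
    min_anchors: int = 5

    def __post_init__(self) -> None:
        if self.mass_tol_da <= 0 or self.rt_window_min <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class QuantMatrix:
    """Proteoform x sample abundance table with aligned metadata.

    ``values`` rows are indexed by proteoform_id, columns by sample_id.
    Intensity mode stores log2 ratios (relative to the per-proteoform
    across-sample median) with NaN for absent cells; counts mode stores
    nonnegative integers with no absent cells.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # indexed by sample_id: batch, pmi_hours, ...
    proteoforms: pd.DataFrame  # indexed by proteoform_id: catalog fields
    mode: str  # "intensity" | "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("intensity", "counts"):
            raise ValueError("mode must be 'intensity' or 'counts'")
        if not self.values.columns.is_unique or not self.values.index.is_unique:
            raise ValueError("row/column labels must be unique")
        if self.mode == "counts" and self.values.isna().any().any():
            raise ValueError("counts matrix must not contain absent cells")


@dataclass
class NetworkConfig:
    """Co-abundance network settings (weighted correlation network)."""

    min_samples_observed: int = 51
    soft_power: int = 6
    sign: str = "unsigned"
    min_module_size: int = 5
    merge_height: float = 0.15
    cut_height: float = 0.99
    impute_rank: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.merge_height < 1.0:
            raise ValueError("merge_height must lie in (0, 1)")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.sign not in ("unsigned", "signed"):
            raise ValueError("sign must be 'unsigned' or 'signed'")


@dataclass
class CleavageSite:
    """A proteolytic cleavage at the bond between residues i and i+1."""

    accession: str
    site: int  # 1-based bond index
    terminus: str  # "N" | "C"
    dibasic: bool = False
    structure_eligible: bool = True
    mean_flank_plddt: Optional[float] = None
    known: Optional[bool] = None


@dataclass
class AbetaLabel:
    """Amyloid-beta truncation nomenclature: Abeta_x-y on the Abeta axis.

    Position 1 of the amyloid-beta axis is APP residue 672 (the
    beta-secretase cleavage product's first residue). ``terminal_class``
    groups C-termini: 'x_42_43' (plaque-associated extended forms),
    'x_le_40' (vascular-amyloid-associated truncated forms); y = 41 is
    left 'unclassified'.
    """

    x: int
    y: int
    terminal_class: str
    ptms: tuple = ()
    pyroglu: bool = False

    @property
    def label(self) -> str:
        prefix = "pE" if self.pyroglu else ""
        return f"Abeta_{prefix}{self.x}-{self.y}"


@dataclass
class Warp:
    """Monotone piecewise-linear retention-time map onto the reference run."""

    x: np.ndarray  # anchor RTs in this run (sorted, strictly increasing)
    y: np.ndarray  # fitted reference RTs (non-decreasing)
    identity: bool = False

    def __call__(self, rt):
        rt = np.asarray(rt, dtype=float)
        if self.identity or len(self.x) == 0:
            return rt
        return np.interp(rt, self.x, self.y)


WarpFn = Callable[[np.ndarray], np.ndarray]
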