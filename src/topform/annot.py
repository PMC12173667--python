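"""Sequence-context annotation of proteoforms.

Maps truncation coordinates onto reference sequences to enumerate proteolytic
cleavage sites, assigns amyloid-beta truncation nomenclature (Abeta_x-y with
position 1 at APP residue 672) and the plaque/vascular-amyloid terminal
classes, tabulates modification frequencies, relates cleavage sites to
dibasic convertase motifs and to local structural confidence (pLDDT), and
tests within-module modification enrichment by Fisher's exact test computed
from the hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AbetaLabel, CleavageSite, ReferenceEntry

logger = logging.getLogger(__name__)

DIBASIC_PAIRS = {"KK", "KR", "RK", "RR"}

ABETA_APP_START = 672  # APP residue carrying amyloid-beta position 1
ABETA_APP_END = 713  # canonical Abeta(1-42) C-terminus on APP


# --------------------------------------------------------------------------
# cleavage mapping
# --------------------------------------------------------------------------


def map_to_reference(
    start: int, end: int, entry: ReferenceEntry
) -> list[CleavageSite]:
    """Cleavage sites implied by a proteoform's truncation coordinates.

    An N-terminal cleavage at bond start-1 is recorded when start > 1, except
    start = 2 on a Met-initiated reference (N-terminal methionine excision is
    a modification, not a cleavage). A C-terminal cleavage at bond ``end`` is
    recorded when end < length. A site qualifies for structural analysis only
    when the cleavage is not within the first or last three residues
    (start > 4 for N-sites; end < length - 3 for C-sites).
    """
    length = len(entry.sequence)
    if not (1 <= start <= end <= length):
        raise ValueError(
            f"coordinates {start}-{end} out of range for {entry.accession} (len {length})"
        )
    sites = []
    if start > 1 and not (start == 2 and entry.sequence[0] == "M"):
        sites.append(_make_site(entry, start - 1, "N", structure_ok=start > 4))
    if end < length:
        sites.append(_make_site(entry, end, "C", structure_ok=end < length - 3))
    return sites


def _make_site(entry: ReferenceEntry, bond: int, terminus: str, structure_ok: bool) -> CleavageSite:
    pair = entry.sequence[bond - 1 : bond + 1]
    return CleavageSite(
        accession=entry.accession,
        site=bond,
        terminus=terminus,
        dibasic=pair in DIBASIC_PAIRS,
        structure_eligible=structure_ok,
    )


def catalog_cleavage_sites(
    catalog: pd.DataFrame, reference: Mapping[str, ReferenceEntry]
) -> list[CleavageSite]:
    """Unique cleavage sites implied by a proteoform catalog."""
    seen = set()
    sites = []
    for _, row in catalog.iterrows():
        entry = reference.get(row["accession"])
        if entry is None:
            continue
        for site in map_to_reference(int(row["start"]), int(row["end"]), entry):
            key = (site.accession, site.site)
            if key not in seen:
                seen.add(key)
                sites.append(site)
    return sites


# --------------------------------------------------------------------------
# amyloid-beta nomenclature
# --------------------------------------------------------------------------


def abeta_label(
    start: int,
    end: int,
    mods: Iterable[str] = (),
    region_start: int = ABETA_APP_START,
    region_end: int = ABETA_APP_END,
) -> AbetaLabel:
    """Amyloid-beta truncation label for a proteoform on APP coordinates.

    Position x = APP start - (region_start - 1); y likewise for the end.
    C-termini at 42/43 form the plaque-associated extended class, <= 40 the
    vascular-amyloid-associated truncated class; y = 41 stays unclassified.
    A proteoform must overlap the amyloid region generously (C-terminal
    extension to y = 43 is allowed).
    """
    offset = region_start - 1
    x = start - offset
    y = end - offset
    if x < 1 or y < x or y > (region_end - offset) + 1:
        raise ValueError(f"proteoform {start}-{end} lies outside the amyloid-beta region")
    mods = list(mods)
    pyroglu = any("pyroglutamate" in m for m in mods)
    if y in (42, 43):
        cls = "x_42_43"
    elif y <= 40:
        cls = "x_le_40"
    else:
        cls = "unclassified"
    return AbetaLabel(x=x, y=y, terminal_class=cls, ptms=tuple(mods), pyroglu=pyroglu)


def abeta_coordinates(label: AbetaLabel, region_start: int = ABETA_APP_START) -> tuple[int, int]:
    """Inverse of :func:`abeta_label`: APP (start, end) for an Abeta_x-y label."""
    offset = region_start - 1
    return label.x + offset, label.y + offset


def abeta_map_table(
    catalog: pd.DataFrame, region_start: int = ABETA_APP_START,
    region_end: int = ABETA_APP_END, gene: str = "APP",
) -> pd.DataFrame:
    """Abeta_x-y map of a catalog's APP proteoforms inside the amyloid region."""
    rows = []
    sub = catalog[catalog["gene"] == gene]
    for _, r in sub.iterrows():
        mods = _mods_of(r)
        try:
            lab = abeta_label(int(r["start"]), int(r["end"]), mods,
                              region_start, region_end)
        except ValueError:
            continue
        rows.append(
            dict(proteoform_id=r.get("proteoform_id"), label=lab.label, x=lab.x,
                 y=lab.y, terminal_class=lab.terminal_class, ptms=";".join(mods))
        )
    return pd.DataFrame(rows)


def _mods_of(row) -> list[str]:
    raw = row.get("mods", "")
    if isinstance(raw, str) and raw:
        return [tok.split("@")[0] for tok in raw.split(";")]
    return []


# --------------------------------------------------------------------------
# modification frequencies
# --------------------------------------------------------------------------


def ptm_frequency_table(catalog: pd.DataFrame, top: int = 10) -> pd.DataFrame:
    """Percent of proteoforms carrying each modification class (top-n).

    Presence-based: a proteoform with two oxidations counts once, so every
    percentage is at most 100.
    """
    if catalog.empty:
        return pd.DataFrame(columns=["modification", "percent", "n_proteoforms"])
    n = len(catalog)
    counts: dict = {}
    for _, row in catalog.iterrows():
        for mod in set(_mods_of(row)):
            counts[mod] = counts.get(mod, 0) + 1
    table = pd.DataFrame(
        [{"modification": m, "n_proteoforms": c, "percent": 100.0 * c / n}
         for m, c in counts.items()]
    )
    if table.empty:
        return pd.DataFrame(columns=["modification", "percent", "n_proteoforms"])
    return (
        table.sort_values(["percent", "modification"], ascending=[False, True])
        .head(top)
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# structural context of cleavage sites
# --------------------------------------------------------------------------


@dataclass
class StructureContext:
    """Flank pLDDT means of cleavage sites against the cleaved-protein background."""

    site_means: np.ndarray
    background: np.ndarray
    ks_stat: float
    ks_p: float
    median_shift: float  # median(site means) - median(background)
    frac_below_50: float
    n_sites_used: int
    n_sites_skipped: int


def flank_mean_plddt(track: np.ndarray, bond: int, flank: int = 3) -> Optional[float]:
    """Mean pLDDT over the residues within +/- ``flank`` of the cleaved bond.

    The bond between residues i and i+1 has flanking residues i-2..i+3 for
    flank = 3 (three per side); windows are clipped at the termini and need
    at least four residues.
    """
    length = len(track)
    lo = max(1, bond - flank + 1)
    hi = min(length, bond + flank)
    window = track[lo - 1 : hi]
    if len(window) < 4:
        return None
    return float(np.mean(window))


def cleavage_structure_context(
    sites: Sequence[CleavageSite],
    plddt_tracks: Mapping[str, np.ndarray],
    flank: int = 3,
    only_structure_eligible: bool = True,
) -> StructureContext:
    """Compare cleavage-site flank pLDDT means with the cleaved-protein background.

    Background pools the per-residue pLDDT of every protein contributing at
    least one usable site; a two-sample Kolmogorov-Smirnov test quantifies
    the distribution shift. Sites without a track (or with too small a
    window) are skipped and counted.
    """
    means, used_accessions = [], set()
    skipped = 0
    for site in sites:
        if only_structure_eligible and not site.structure_eligible:
            continue
        track = plddt_tracks.get(site.accession)
        if track is None:
            skipped += 1
            continue
        m = flank_mean_plddt(np.asarray(track, dtype=float), site.site, flank)
        if m is None:
            skipped += 1
            continue
        site.mean_flank_plddt = m
        means.append(m)
        used_accessions.add(site.accession)
    site_means = np.asarray(means)
    background = (
        np.concatenate([np.asarray(plddt_tracks[a], dtype=float)
                        for a in sorted(used_accessions)])
        if used_accessions
        else np.array([])
    )
    if len(site_means) and len(background):
        ks_stat, ks_p = sps.ks_2samp(site_means, background)
        shift = float(np.median(site_means) - np.median(background))
    else:
        ks_stat, ks_p, shift = np.nan, np.nan, np.nan
    frac = float(np.mean(site_means < 50.0)) if len(site_means) else np.nan
    return StructureContext(
        site_means=site_means,
        background=background,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        median_shift=shift,
        frac_below_50=frac,
        n_sites_used=len(site_means),
        n_sites_skipped=skipped,
    )


# --------------------------------------------------------------------------
# dibasic cleavage maps
# --------------------------------------------------------------------------


def dibasic_bonds(sequence: str) -> list[int]:
    """All bond indices i whose residues (i, i+1) form a dibasic motif."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i : i + 2] in DIBASIC_PAIRS
    ]


def dibasic_cleavage_map(
    entry: ReferenceEntry,
    observed_sites: Iterable[int],
    known_sites: Optional[Iterable[int]] = None,
) -> tuple[pd.DataFrame, float, list[int]]:
    """Relate observed cleavage sites to dibasic motifs and the known-site list.

    Returns (site table, dibasic coverage fraction, novel sites). Coverage is
    the fraction of dibasic bonds with an observed cleavage; novel sites are
    observed sites absent from the known list.
    """
    observed = sorted(set(int(s) for s in observed_sites))
    known = sorted(set(int(s) for s in known_sites)) if known_sites is not None else []
    dib = dibasic_bonds(entry.sequence)
    rows = [
        dict(
            site=s,
            dibasic=s in dib,
            known=(s in known) if known_sites is not None else None,
            pair=entry.sequence[s - 1 : s + 1],
        )
        for s in observed
    ]
    coverage = (
        float(np.mean([d in observed for d in dib])) if dib else float("nan")
    )
    novel = [s for s in observed if s not in known] if known_sites is not None else []
    return pd.DataFrame(rows, columns=["site", "dibasic", "known", "pair"]), coverage, novel


# --------------------------------------------------------------------------
# Fisher exact enrichment
# --------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test via hypergeometric enumeration.

    Returns (odds ratio, p). The p-value sums the probabilities of all tables
    with the same margins no more probable than the observed one; the odds
    ratio is the sample estimate with a Haldane 0.5 correction when any cell
    is zero.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return np.nan, 1.0
    rv = sps.hypergeom(n, col1, row1)
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-9)]))
    p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        oddsratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsratio = (a * d) / (b * c)
    return float(oddsratio), p


def module_modification_enrichment(
    member_ids: Sequence, catalog: pd.DataFrame, modification: str
) -> dict:
    """Fisher enrichment of a modification within a module vs the catalog."""
    member_ids = list(member_ids)
    if not member_ids:
        raise ValueError("module is empty")
    has_mod = catalog.apply(lambda r: modification in _mods_of(r), axis=1)
    in_mod = catalog["proteoform_id"].isin(member_ids)
    a = int((in_mod & has_mod).sum())
    b = int((in_mod & ~has_mod).sum())
    c = int((~in_mod & has_mod).sum())
    d = int((~in_mod & ~has_mod).sum())
    oddsratio, p = fisher_exact_2x2([[a, b], [c, d]])
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": oddsratio,
        "p": p,
        "modification": modification,
        "n_module": len(member_ids),
    }
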