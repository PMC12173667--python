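"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: PrSM tables and MS1 feature tables as TSV (one file per LC-MS run),
the protein database as FASTA with ``key=value`` header tokens (tier, gene,
decoy flag), the cohort as CSV, per-residue pLDDT tracks as a long CSV and
quantification matrices as CSV with companion metadata tables.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import FEATURE_COLUMNS, PRSM_COLUMNS, QuantMatrix, ReferenceEntry

PRSM_DTYPES = {
    "sample_id": str,
    "scan": int,
    "accession": str,
    "tier": str,
    "gene": str,
    "proteoform": str,
    "start": int,
    "end": int,
    "mass_da": float,
    "rt_min": float,
    "evalue": float,
    "intensity": float,
    "is_decoy": bool,
}


def write_prsm_tsv(df: pd.DataFrame, path: str) -> None:
    df.loc[:, PRSM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_prsm_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "is_decoy": bool})
    missing = set(PRSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing PrSM columns {sorted(missing)}")
    return df[PRSM_COLUMNS]


def write_feature_tsv(df: pd.DataFrame, path: str) -> None:
    df.loc[:, FEATURE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df[FEATURE_COLUMNS]


def write_fasta(entries: Iterable[ReferenceEntry], path: str) -> None:
    records = []
    for e in entries:
        desc = f"gene={e.gene} tier={e.tier} decoy={int(e.is_decoy)}"
        records.append(SeqRecord(Seq(e.sequence), id=e.accession, description=desc))
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> list[ReferenceEntry]:
    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        tokens = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        entries.append(
            ReferenceEntry(
                accession=rec.id,
                gene=tokens.get("gene", rec.id),
                tier=tokens.get("tier", "canonical"),
                sequence=str(rec.seq),
                is_decoy=tokens.get("decoy", "0") == "1",
            )
        )
    return entries


def write_plddt_csv(entries: Iterable[ReferenceEntry], path: str) -> None:
    rows = []
    for e in entries:
        if e.plddt is None:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "accession": e.accession,
                    "position": np.arange(1, len(e.plddt) + 1),
                    "plddt": e.plddt,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["accession", "position", "plddt"]
    )
    out.to_csv(path, index=False)


def read_plddt_csv(path: str) -> dict:
    """Load pLDDT tracks as a dict accession -> 1-indexed-by-position array."""
    df = pd.read_csv(path)
    tracks = {}
    for acc, grp in df.groupby("accession"):
        grp = grp.sort_values("position")
        tracks[acc] = grp["plddt"].to_numpy(dtype=float)
    return tracks


def write_quant_matrix(qm: QuantMatrix, directory: str, prefix: str) -> None:
    os.makedirs(directory, exist_ok=True)
    qm.values.to_csv(os.path.join(directory, f"{prefix}_values.csv"))
    qm.samples.to_csv(os.path.join(directory, f"{prefix}_samples.csv"))
    qm.proteoforms.to_csv(os.path.join(directory, f"{prefix}_proteoforms.csv"))
    with open(os.path.join(directory, f"{prefix}_mode.json"), "w") as fh:
        json.dump({"mode": qm.mode}, fh)


def read_quant_matrix(directory: str, prefix: str) -> QuantMatrix:
    values = pd.read_csv(os.path.join(directory, f"{prefix}_values.csv"), index_col=0)
    samples = pd.read_csv(
        os.path.join(directory, f"{prefix}_samples.csv"), index_col=0
    )
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    proteoforms = pd.read_csv(
        os.path.join(directory, f"{prefix}_proteoforms.csv"), index_col=0
    )
    with open(os.path.join(directory, f"{prefix}_mode.json")) as fh:
        mode = json.load(fh)["mode"]
    if mode == "counts":
        values = values.astype(int)
    return QuantMatrix(values=values, samples=samples, proteoforms=proteoforms, mode=mode)
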