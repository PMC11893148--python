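"""Reading and validating precursor reports, FASTA files and design tables.

The default column map targets Spectronaut-style long-format reports; every
mapping is user-overridable so other report dialects with the same content
can be ingested without code changes.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import PRECURSOR_COLUMNS, PrecursorTable, StudyDesign

logger = logging.getLogger(__name__)

#: canonical field -> Spectronaut report column
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "run_id": "R.FileName",
    "condition": "R.Condition",
    "replicate": "R.Replicate",
    "protein_group": "PG.ProteinGroups",
    "stripped_sequence": "PEP.StrippedSequence",
    "modified_sequence": "EG.ModifiedSequence",
    "precursor_id": "EG.PrecursorId",
    "quantity": "FG.Quantity",
    "precursor_qvalue": "EG.Qvalue",
    "pg_qvalue": "PG.Qvalue",
}

_DELIMITERS = "\t,;"

#: amino-acid alphabet accepted in FASTA sequences (20 standard + ambiguity)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        # single-column fallback: pick the delimiter that appears most
        counts = {d: sample.count(d) for d in _DELIMITERS}
        return max(counts, key=counts.get) if max(counts.values()) else "\t"


def read_precursor_report(path, column_map: dict[str, str] | None = None) -> PrecursorTable:
    """Parse a long-format precursor quantification report (TSV/CSV/;SV).

    Unparseable or non-positive quantities become missing (NaN) with a
    logged count.  Duplicate (precursor_id, run_id) rows collapse to the
    one with the lowest precursor q-value, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [col for col in cmap.values() if col not in raw.columns]
    if missing_cols:
        raise ValueError(
            f"report {path} is missing mapped columns: {missing_cols}; "
            f"header has {list(raw.columns)}"
        )
    df = pd.DataFrame({field: raw[col] for field, col in cmap.items()})
    if df.empty:
        raise ValueError(f"report {path} contains no data rows")

    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    for col in ("precursor_qvalue", "pg_qvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    qty = pd.to_numeric(df["quantity"], errors="coerce").astype(float)
    n_nonpos = int((qty <= 0).sum())
    if n_nonpos:
        logger.warning("%d quantities <= 0 treated as missing", n_nonpos)
        qty = qty.where(qty > 0)
    df["quantity"] = qty

    dup_mask = df.duplicated(subset=["precursor_id", "run_id"], keep=False)
    if dup_mask.any():
        n_groups = df.loc[dup_mask, ["precursor_id", "run_id"]].drop_duplicates().shape[0]
        logger.warning(
            "%d duplicated (precursor_id, run_id) pairs collapsed to lowest precursor q-value",
            n_groups,
        )
        df = (
            df.sort_values("precursor_qvalue", kind="stable")
            .drop_duplicates(subset=["precursor_id", "run_id"], keep="first")
            .sort_index()
        )
    return PrecursorTable(df.reset_index(drop=True))


def _accession_from_header(header_token: str) -> str:
    """UniProt 'db|ACC|name' headers reduce to ACC; otherwise the token itself."""
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_token


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into an accession -> sequence mapping."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(record.id)
        seq = str(record.seq).strip().upper()
        if not seq:
            raise ValueError(f"empty sequence for accession {acc!r} in {path}")
        if acc in sequences:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in accession {acc!r}")
        sequences[acc] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_design(path, comparisons: list[tuple[str, str]] | None = None) -> StudyDesign:
    """Read a run-design TSV (run_id, condition, replicate [, batch, covariates])."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    samples = pd.read_csv(path, sep=sep)
    samples["run_id"] = samples["run_id"].astype(str)
    samples["condition"] = samples["condition"].astype(str)
    known = {"run_id", "condition", "replicate", "batch"}
    covariates = [c for c in samples.columns if c not in known]
    design = StudyDesign(samples, comparisons or [], covariate_columns=covariates)
    if not design.comparisons:
        conds = design.conditions
        design.comparisons = [(b, a) for i, a in enumerate(conds) for b in conds[i + 1 :]]
    for cond in design.conditions:
        if (samples["condition"] == cond).sum() < 2:
            logger.warning("condition %r has <2 replicates; statistics will skip it", cond)
    return design


def id_rate_summary(table: PrecursorTable) -> pd.DataFrame:
    """Per-run identification counts over rows with observed quantity.

    Returns one row per run plus a 'total' row holding union counts across
    all runs.  Counts are distinct precursors, stripped peptides and
    protein groups.
    """
    if table.df.empty:
        raise ValueError("cannot summarise an empty precursor table")
    obs = table.df[table.df["quantity"].notna()]
    rows = []
    for run_id, grp in obs.groupby("run_id", sort=True):
        rows.append(
            {
                "run_id": run_id,
                "n_precursors": grp["precursor_id"].nunique(),
                "n_peptides": grp["stripped_sequence"].nunique(),
                "n_protein_groups": grp["protein_group"].nunique(),
            }
        )
    rows.append(
        {
            "run_id": "total",
            "n_precursors": obs["precursor_id"].nunique(),
            "n_peptides": obs["stripped_sequence"].nunique(),
            "n_protein_groups": obs["protein_group"].nunique(),
        }
    )
    return pd.DataFrame(rows)
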