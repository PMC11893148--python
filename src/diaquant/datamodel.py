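"""Core data containers shared across the pipeline.

The pipeline's currency is the long-format precursor table (one row per
precursor x run), which is pivoted into a log2 peptide matrix for
normalization and statistics, and summarised into per-method protein
quantification tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: canonical column order of a PrecursorTable data frame
PRECURSOR_COLUMNS = [
    "run_id",
    "condition",
    "replicate",
    "protein_group",
    "stripped_sequence",
    "modified_sequence",
    "precursor_id",
    "quantity",
    "precursor_qvalue",
    "pg_qvalue",
]


@dataclass
class PrecursorTable:
    """Long-format precursor quantification records.

    ``df`` holds one row per (precursor_id, run_id); ``quantity`` is a
    positive linear-scale intensity or NaN (missing / censored).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PRECURSOR_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"precursor table missing columns: {missing}")
        self.df = self.df[PRECURSOR_COLUMNS].reset_index(drop=True)

    @property
    def run_ids(self) -> list[str]:
        return list(pd.unique(self.df["run_id"]))

    def copy(self) -> "PrecursorTable":
        return PrecursorTable(self.df.copy())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class StudyDesign:
    """Sample layout and requested condition comparisons.

    ``samples`` has columns run_id, condition, replicate and optionally
    batch plus arbitrary covariate columns.  ``comparisons`` is a list of
    (numerator_condition, denominator_condition) pairs; ratios are reported
    as numerator minus denominator on the log2 scale.
    """

    samples: pd.DataFrame
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = {"run_id", "condition", "replicate"}
        missing = req - set(self.samples.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.samples["run_id"].duplicated().any():
            dup = self.samples.loc[self.samples["run_id"].duplicated(), "run_id"].tolist()
            raise ValueError(f"duplicate run_id in design: {dup}")
        self.samples = self.samples.reset_index(drop=True)
        conds = set(self.samples["condition"])
        for num, den in self.comparisons:
            if num not in conds or den not in conds:
                raise ValueError(f"comparison ({num}, {den}) references unknown condition")

    @property
    def run_ids(self) -> list[str]:
        return self.samples["run_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    def runs_of(self, condition: str) -> list[str]:
        return self.samples.loc[self.samples["condition"] == condition, "run_id"].tolist()

    @property
    def has_batch(self) -> bool:
        return "batch" in self.samples.columns and self.samples["batch"].notna().any()

    def validate_against(self, table: PrecursorTable) -> None:
        """Every run in the precursor table must appear exactly once in the design."""
        table_runs = set(table.df["run_id"])
        design_runs = set(self.run_ids)
        extra = table_runs - design_runs
        if extra:
            raise ValueError(f"runs present in report but absent from design: {sorted(extra)}")


@dataclass
class PeptideMatrix:
    """log2 precursor intensity matrix (rows precursor_id, columns run_id).

    ``row_meta`` maps precursor_id -> (protein_group, stripped_sequence);
    ``normalization_offsets`` records the per-column log2 shift applied by
    median normalization (NaN-free once normalization ran).
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    design: StudyDesign
    normalization_offsets: Optional[pd.Series] = None
    unadjusted_rows: Optional[list[str]] = None
    #: residual degrees of freedom consumed by batch/covariate adjustment
    #: (number of nuisance parameters); honored by downstream t-tests
    df_penalty: int = 0

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.run_ids:
            raise ValueError("peptide matrix columns must equal design run order")
        if not self.values.index.equals(self.row_meta.index):
            raise ValueError("row_meta index must equal matrix index")

    def copy(self) -> "PeptideMatrix":
        return PeptideMatrix(
            self.values.copy(),
            self.row_meta.copy(),
            self.design,
            None if self.normalization_offsets is None else self.normalization_offsets.copy(),
            None if self.unadjusted_rows is None else list(self.unadjusted_rows),
            self.df_penalty,
        )

    def linear(self) -> pd.DataFrame:
        """Back-transform to linear-scale intensities (NaN preserved)."""
        return np.power(2.0, self.values)


@dataclass
class ProteinQuantTable:
    """Protein x sample quantification for one method.

    ``values`` is linear-scale for iBAQ/Hi3 and log2-scale for MaxLFQ
    profiles; ``linear_values``/``log2_values`` expose both scales.
    """

    method: str
    values: pd.DataFrame
    n_peptides: pd.Series
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"iBAQ", "Hi3", "MaxLFQ"}:
            raise ValueError(f"unknown quantification method {self.method!r}")
        missing = set(self.values.index) - set(self.n_peptides.index)
        if missing:
            raise ValueError(f"n_peptides missing for proteins: {sorted(missing)[:5]}")

    @property
    def is_log2(self) -> bool:
        return self.method == "MaxLFQ"

    def log2_values(self) -> pd.DataFrame:
        if self.is_log2:
            return self.values
        return np.log2(self.values)

    def linear_values(self) -> pd.DataFrame:
        if self.is_log2:
            return np.power(2.0, self.values)
        return self.values
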