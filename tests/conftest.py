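import numpy as np
import pandas as pd
import pytest

from diaquant.datamodel import PrecursorTable, StudyDesign
from diaquant.synthetic_data import SimulationConfig, generate_study

TOY_COLUMNS = [
    "R.FileName", "R.Condition", "R.Replicate", "PG.ProteinGroups",
    "PEP.StrippedSequence", "EG.ModifiedSequence", "EG.PrecursorId",
    "FG.Quantity", "EG.Qvalue", "PG.Qvalue",
]


def toy_report_rows():
    """4 valid precursor rows: 3 precursors from 2 peptides of 1 protein in run A, 1 row in run B."""
    return [
        ["runA", "ctrl", 1, "P001", "PEPTIDEK", "_PEPTIDEK_", "_PEPTIDEK_.2", 1000.0, 0.001, 0.001],
        ["runA", "ctrl", 1, "P001", "PEPTIDEK", "_PEPTIDEK_", "_PEPTIDEK_.3", 500.0, 0.002, 0.001],
        ["runA", "ctrl", 1, "P001", "SEQWENCEK", "_SEQWENCEK_", "_SEQWENCEK_.2", 800.0, 0.004, 0.001],
        ["runB", "trt", 1, "P001", "PEPTIDEK", "_PEPTIDEK_", "_PEPTIDEK_.2", 1200.0, 0.003, 0.002],
    ]


@pytest.fixture
def toy_report_path(tmp_path):
    df = pd.DataFrame(toy_report_rows(), columns=TOY_COLUMNS)
    path = tmp_path / "report.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def make_table(rows):
    """PrecursorTable from canonical-column row tuples."""
    from diaquant.datamodel import PRECURSOR_COLUMNS

    return PrecursorTable(pd.DataFrame(rows, columns=PRECURSOR_COLUMNS))


def make_design(conditions, reps, batches=None, comparisons=None):
    rows = []
    i = 0
    for cond in conditions:
        for r in range(1, reps + 1):
            row = {"run_id": f"{cond}_R{r}", "condition": cond, "replicate": r}
            if batches is not None:
                row["batch"] = batches[i]
            rows.append(row)
            i += 1
    comps = comparisons or [(c, conditions[0]) for c in conditions[1:]]
    return StudyDesign(pd.DataFrame(rows), comps)


@pytest.fixture(scope="session")
def small_study():
    """Deterministic 2-condition study with regulation, oxidation and dropout."""
    cfg = SimulationConfig(
        n_proteins=60,
        fraction_regulated=0.2,
        oxidation_fraction=0.05,
        qvalue_fail_fraction=0.02,
        dropout_midpoint=11.0,
        seed=42,
    )
    return cfg, generate_study(cfg)
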