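"""Synthetic Spectronaut-style study generator with known ground truth.

The generator emulates the features of a DIA-MS precursor report the
pipeline has to handle: a hierarchical intensity model (protein base
level, peptide ionisation offset, replicate noise), condition effects on a
regulated subset, additive batch shifts, intensity-dependent logistic
dropout, oxidized-Met precursor variants and q-values straddling the
filter threshold.  A FASTA is emitted whose tryptic digestion recovers
exactly the generated peptides, so iBAQ observable counts are
self-consistent.  Generation is a pure function of (config, seed).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import PrecursorTable, StudyDesign

#: residues used for synthetic peptides: no K/R (interior cleavage sites)
#: and no P (cleavage suppression) so concatenation digests back exactly
_PEPTIDE_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass
class SimulationConfig:
    """Study-generating parameters; defaults describe a small two-condition LFQ study."""

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (3, 8)
    n_conditions: int = 2
    replicates_per_condition: int = 3
    base_log2_intensity_mean: float = 16.0
    base_log2_intensity_sd: float = 2.0
    peptide_offset_sd: float = 1.5
    replicate_noise_sd: float = 0.25
    fraction_regulated: float = 0.2
    true_log2_fc: float = 1.0
    n_batches: int = 1
    batch_shift_log2: float = 0.0
    dropout_midpoint: float | None = None  # log2 intensity at 50% dropout; None = no dropout
    dropout_steepness: float = 1.0
    oxidation_fraction: float = 0.0
    qvalue_fail_fraction: float = 0.0  # fraction of rows with precursor q above 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.replicates_per_condition < 1 or self.n_conditions < 1:
            raise ValueError("need >=1 protein, condition and replicate")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein range invalid")
        for name in ("base_log2_intensity_sd", "peptide_offset_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_regulated", "oxidation_fraction", "qvalue_fail_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated report."""

    proteins: pd.DataFrame  # protein_group, regulated, true_log2_fc
    sample_batch_shift: pd.Series  # run_id -> log2 shift
    true_log2: pd.DataFrame  # precursor x run true log2 values (pre-dropout)
    config: SimulationConfig = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "proteins": self.proteins.to_dict(orient="records"),
            "sample_batch_shift": self.sample_batch_shift.to_dict(),
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_peptide(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(6, 20))
        pep = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length)) + "K"
        if pep not in existing:
            existing.add(pep)
            return pep


def generate_study(
    config: SimulationConfig,
) -> tuple[PrecursorTable, StudyDesign, SyntheticTruth, dict[str, str]]:
    """Generate (PrecursorTable, StudyDesign, SyntheticTruth, FASTA mapping)."""
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins
    conditions = [f"C{i + 1}" for i in range(config.n_conditions)]

    # --- design -----------------------------------------------------------
    rows = []
    sample_idx = 0
    for cond in conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            batch = f"B{sample_idx % config.n_batches + 1}"
            rows.append({"run_id": f"{cond}_R{rep}", "condition": cond, "replicate": rep, "batch": batch})
            sample_idx += 1
    samples = pd.DataFrame(rows)
    if config.n_batches <= 1:
        samples = samples.drop(columns="batch")
    comparisons = [(c, conditions[0]) for c in conditions[1:]]
    design = StudyDesign(samples, comparisons)
    batch_shift = pd.Series(0.0, index=design.run_ids)
    if config.n_batches > 1:
        for i, run in enumerate(design.run_ids):
            b = i % config.n_batches
            batch_shift[run] = b * config.batch_shift_log2

    # --- proteins, regulation, peptides ----------------------------------
    accessions = [f"SYN{i + 1:05d}" for i in range(n_prot)]
    n_regulated = math.floor(n_prot * config.fraction_regulated)
    regulated = np.zeros(n_prot, dtype=bool)
    regulated[rng.permutation(n_prot)[:n_regulated]] = True
    base = rng.normal(config.base_log2_intensity_mean, config.base_log2_intensity_sd, n_prot)
    lo, hi = config.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=n_prot)

    existing: set[str] = set()
    fasta: dict[str, str] = {}
    precursor_rows = []
    true_cols: dict[str, list[float]] = {r: [] for r in design.run_ids}
    precursor_ids: list[str] = []
    prot_of_precursor: list[str] = []

    cond_effect = {c: (config.true_log2_fc if j > 0 else 0.0) for j, c in enumerate(conditions)}

    for p in range(n_prot):
        acc = accessions[p]
        peptides = [_random_peptide(rng, existing) for _ in range(n_peps[p])]
        # decoy flank shorter than any observable peptide so digestion
        # recovers exactly the generated peptides
        fasta[acc] = "".join(peptides) + "AAAGG"
        offsets = rng.normal(0.0, config.peptide_offset_sd, n_peps[p])
        for pep, off in zip(peptides, offsets):
            modseq = f"_{pep}_"
            precursor_id = f"{modseq}.2"
            precursor_ids.append(precursor_id)
            prot_of_precursor.append(acc)
            for run, cond in zip(design.run_ids, design.samples["condition"]):
                effect = cond_effect[cond] if regulated[p] else 0.0
                value = base[p] + off + effect + batch_shift[run] + (
                    rng.normal(0.0, config.replicate_noise_sd) if config.replicate_noise_sd > 0 else 0.0
                )
                true_cols[run].append(value)
                precursor_rows.append(
                    {
                        "run_id": run,
                        "condition": cond,
                        "replicate": int(run.rsplit("R", 1)[1]),
                        "protein_group": acc,
                        "stripped_sequence": pep,
                        "modified_sequence": modseq,
                        "precursor_id": precursor_id,
                        "true_log2": value,
                    }
                )

    df = pd.DataFrame(precursor_rows)

    # --- oxidized-Met variants -------------------------------------------
    if config.oxidation_fraction > 0:
        uniq = pd.Index(precursor_ids)
        with_met = [pid for pid in uniq if "M" in pid]
        n_ox = math.floor(len(uniq) * config.oxidation_fraction)
        chosen = list(rng.permutation(with_met)[:n_ox])
        if chosen:
            ox_rows = df[df["precursor_id"].isin(chosen)].copy()
            ox_rows["modified_sequence"] = ox_rows["modified_sequence"].str.replace(
                "M", "M[Oxidation (M)]", n=1, regex=False
            )
            ox_rows["precursor_id"] = ox_rows["modified_sequence"] + ".2"
            ox_rows["true_log2"] = ox_rows["true_log2"] - 2.0  # oxidized forms ionise lower
            df = pd.concat([df, ox_rows], ignore_index=True)

    # --- dropout, q-values, quantities -----------------------------------
    n_rows = len(df)
    quantity = np.power(2.0, df["true_log2"].to_numpy())
    if config.dropout_midpoint is not None:
        p_drop = 1.0 / (
            1.0 + np.exp(config.dropout_steepness * (df["true_log2"].to_numpy() - config.dropout_midpoint))
        )
        drop = rng.random(n_rows) < p_drop
        quantity = np.where(drop, np.nan, quantity)
    prec_q = rng.uniform(0.0, 0.009, n_rows)
    if config.qvalue_fail_fraction > 0:
        fail = rng.random(n_rows) < config.qvalue_fail_fraction
        prec_q = np.where(fail, rng.uniform(0.011, 0.5, n_rows), prec_q)
    pg_q = rng.uniform(0.0, 0.005, n_rows)

    table_df = df.drop(columns="true_log2").assign(
        quantity=quantity,
        precursor_qvalue=np.round(prec_q, 6),
        pg_qvalue=np.round(pg_q, 6),
    )
    table = PrecursorTable(table_df)

    proteins = pd.DataFrame(
        {
            "protein_group": accessions,
            "regulated": regulated,
            "true_log2_fc": np.where(regulated, config.true_log2_fc, 0.0),
        }
    )
    true_log2 = (
        df[df["modified_sequence"].str.find("[") < 0]
        .pivot_table(index="precursor_id", columns="run_id", values="true_log2")
        .reindex(columns=design.run_ids)
    )
    truth = SyntheticTruth(proteins, batch_shift, true_log2, config)
    return table, design, truth, fasta


def write_study(out_dir, table: PrecursorTable, design: StudyDesign, truth: SyntheticTruth, fasta: dict[str, str]) -> None:
    """Write report.tsv, design.tsv, proteome.fasta and truth.json to a directory."""
    from .io_ingest import DEFAULT_COLUMN_MAP, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = table.df.rename(columns=DEFAULT_COLUMN_MAP)
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    design.samples.to_csv(out / "design.tsv", sep="\t", index=False)
    write_fasta(fasta, out / "proteome.fasta")
    truth.to_json(out / "truth.json")


def truth_evaluation(
    protein_stats: pd.DataFrame, truth: SyntheticTruth, alpha: float = 0.05
) -> dict[str, float | None]:
    """Score a protein statistics table against the generating truth.

    type_i_error: fraction of non-regulated proteins with protein_p < alpha.
    power: fraction of regulated proteins with adj_p < alpha.
    fc_bias / fc_rmse: error of median_log2_ratio vs true fold change over
    regulated proteins.  Power is None when nothing is regulated.
    """
    merged = protein_stats.merge(truth.proteins, on="protein_group", how="inner")
    null = merged[~merged["regulated"]]
    reg = merged[merged["regulated"]]
    type_i = float((null["protein_p"] < alpha).mean()) if len(null) else None
    power = float((reg["adj_p"] < alpha).mean()) if len(reg) else None
    if len(reg):
        err = reg["median_log2_ratio"] - reg["true_log2_fc"]
        bias = float(err.mean())
        rmse = float(np.sqrt((err**2).mean()))
    else:
        bias = rmse = None
    return {"type_i_error": type_i, "power": power, "fc_bias": bias, "fc_rmse": rmse}
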