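"""Filtering, log2 transform, median normalization and batch adjustment.

q-value filtering censors quantities (rows are retained) so identification
summaries remain computable pre and post filter from one table.  Missing
values are never imputed anywhere in the pipeline; downstream statistics
use complete cases per comparison.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import PeptideMatrix, PrecursorTable, StudyDesign

logger = logging.getLogger(__name__)

#: modification-tag substrings identifying oxidized methionine, covering
#: the common report dialects
DEFAULT_OXIDATION_TAGS = ("M[Oxidation", "Oxidation (M)", "M(ox)", "M[+16]")


def filter_qvalues(
    table: PrecursorTable, max_precursor_q: float = 0.01, max_pg_q: float = 0.01
) -> PrecursorTable:
    """Censor quantities whose identification fails the q-value thresholds."""
    for name, thr in (("max_precursor_q", max_precursor_q), ("max_pg_q", max_pg_q)):
        if not (0 < thr <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    df = table.df.copy()
    fail = (df["precursor_qvalue"] > max_precursor_q) | (df["pg_qvalue"] > max_pg_q)
    n_censored = int((fail & df["quantity"].notna()).sum())
    df.loc[fail, "quantity"] = np.nan
    if n_censored:
        logger.info("q-value filter censored %d quantities", n_censored)
    return PrecursorTable(df)


def remove_oxidized_met(
    table: PrecursorTable, tags: tuple[str, ...] = DEFAULT_OXIDATION_TAGS
) -> tuple[PrecursorTable, int]:
    """Drop every precursor whose modified sequence carries an oxidation tag.

    Removal is precursor-wide (all runs).  Returns the filtered table and
    the number of distinct precursors dropped.
    """
    if not tags:
        raise ValueError("tags must be non-empty")
    modseq = table.df["modified_sequence"]
    hit = np.zeros(len(modseq), dtype=bool)
    for tag in tags:
        hit |= modseq.str.contains(tag, regex=False).to_numpy()
    dropped_precursors = table.df.loc[hit, "precursor_id"].nunique()
    out = PrecursorTable(table.df.loc[~hit].reset_index(drop=True))
    if dropped_precursors:
        logger.info("removed %d oxidized-Met precursors", dropped_precursors)
    return out, int(dropped_precursors)


def build_peptide_matrix(table: PrecursorTable, design: StudyDesign) -> PeptideMatrix:
    """Pivot the precursor table into a log2 intensity matrix in design column order."""
    design.validate_against(table)
    log2q = np.log2(table.df["quantity"])
    wide = (
        table.df.assign(log2_quantity=log2q)
        .pivot(index="precursor_id", columns="run_id", values="log2_quantity")
        .reindex(columns=design.run_ids)
        .sort_index()
    )
    if wide.notna().to_numpy().sum() == 0:
        logger.warning("peptide matrix has no observed values after filtering")
    meta = (
        table.df.drop_duplicates("precursor_id")
        .set_index("precursor_id")[["protein_group", "stripped_sequence"]]
        .reindex(wide.index)
    )
    return PeptideMatrix(wide, meta, design)


def condition_wise_filter(matrix: PeptideMatrix, min_fraction: float = 0.5) -> PeptideMatrix:
    """Keep a precursor iff in >=1 condition its observed fraction >= min_fraction."""
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    keep = np.zeros(len(matrix.values), dtype=bool)
    for cond in matrix.design.conditions:
        runs = matrix.design.runs_of(cond)
        frac = matrix.values[runs].notna().mean(axis=1).to_numpy()
        keep |= frac >= min_fraction
    n_dropped = int((~keep).sum())
    logger.info("condition-wise filter kept %d / %d precursors", int(keep.sum()), len(keep))
    out = matrix.copy()
    out.values = out.values.loc[keep]
    out.row_meta = out.row_meta.loc[keep]
    return out


def log2_median_normalize(matrix: PeptideMatrix) -> PeptideMatrix:
    """Median-center each sample to the median of all sample medians.

    offset_j = median_j - median(medians); values_j <- values_j - offset_j.
    After normalization every column median equals the grand reference.
    """
    col_medians = matrix.values.median(axis=0, skipna=True)
    if col_medians.isna().any():
        bad = col_medians.index[col_medians.isna()].tolist()
        raise ValueError(f"cannot normalize: runs with no observed values: {bad}")
    grand = float(np.median(col_medians.to_numpy()))
    offsets = col_medians - grand
    out = matrix.copy()
    out.values = matrix.values.sub(offsets, axis=1)
    out.normalization_offsets = offsets
    return out


def _design_matrix(design: StudyDesign) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Intercept + condition dummies + batch dummies + centered covariates.

    Returns (X, column names, nuisance mask).  Nuisance columns (batch and
    covariates) are the ones subtracted during adjustment; condition
    effects are protected.
    """
    samples = design.samples
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    nuisance = [False]
    conds = design.conditions
    for cond in conds[1:]:
        cols.append((samples["condition"] == cond).to_numpy(float))
        names.append(f"condition[{cond}]")
        nuisance.append(False)
    if design.has_batch:
        batches = list(pd.unique(samples["batch"]))
        for b in batches[1:]:
            cols.append((samples["batch"] == b).to_numpy(float))
            names.append(f"batch[{b}]")
            nuisance.append(True)
    for cov in design.covariate_columns:
        v = pd.to_numeric(samples[cov], errors="raise").to_numpy(float)
        cols.append(v - v.mean())
        names.append(f"covariate[{cov}]")
        nuisance.append(True)
    X = np.column_stack(cols)
    return X, names, np.asarray(nuisance)


def adjust_batch_covariates(matrix: PeptideMatrix, design: StudyDesign | None = None) -> PeptideMatrix:
    """Remove estimated batch/covariate contributions from each precursor row.

    Per row, ordinary least squares of log2 intensity on condition + batch
    + covariates over the observed cells; the fitted batch/covariate part
    is subtracted while condition effects and residuals are retained.
    Rows with too few observations to fit pass through unadjusted and are
    flagged in ``unadjusted_rows``.
    """
    design = design or matrix.design
    X, names, nuisance = _design_matrix(design)
    if not nuisance.any():
        out = matrix.copy()
        out.unadjusted_rows = []
        return out
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient adjustment design (batch/covariates confounded with "
            f"condition); columns: {names}"
        )
    values = matrix.values.to_numpy(copy=True)
    n_params = X.shape[1]
    unadjusted: list[str] = []
    for i, precursor in enumerate(matrix.values.index):
        y = values[i]
        obs = np.isfinite(y)
        n_obs = int(obs.sum())
        if n_obs <= n_params or np.linalg.matrix_rank(X[obs]) < n_params:
            unadjusted.append(precursor)
            continue
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        values[i, obs] = y[obs] - X[obs][:, nuisance] @ beta[nuisance]
    if unadjusted:
        logger.info("%d precursors passed through batch adjustment unadjusted", len(unadjusted))
    out = matrix.copy()
    out.values = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    out.unadjusted_rows = unadjusted
    # adjustment consumes residual degrees of freedom; downstream t-tests
    # subtract this so variance estimates stay calibrated
    out.df_penalty = int(nuisance.sum())
    return out
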