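"""Multivariate QC: PCA, sample correlation, CV summaries, ON/OFF calls.

PCA runs on complete-case features (no imputation anywhere in the
pipeline) with a deterministic sign convention so outputs are bit-stable
across runs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PrecursorTable, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component
    explained_variance_fraction: pd.Series


def pca(matrix: pd.DataFrame, n_components: int | None = None, scale: bool = False) -> PcaResult:
    """Complete-case PCA of a feature x sample log2 matrix.

    Features with any missing value are dropped; samples are the
    observations.  SVD of the column-centered (feature-centered) data;
    each loading vector is signed so its largest-magnitude entry is
    positive.
    """
    complete = matrix.dropna(axis=0, how="any")
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    if complete.shape[0] < 2:
        raise ValueError(
            f"PCA needs >= 2 complete-case features, found {complete.shape[0]}"
        )
    X = complete.to_numpy().T  # samples x features
    X = X - X.mean(axis=0)
    total_var = np.sum(X**2)
    if total_var == 0:
        raise ValueError("zero total variance: all samples identical on complete features")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components or len(s), len(s))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|.| loading entry positive per component
    for c in range(k):
        idx = np.argmax(np.abs(Vt[c]))
        if Vt[c, idx] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=matrix.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=complete.index, columns=comp_names)
    evf = pd.Series(s**2 / total_var, index=comp_names, name="explained_variance_fraction")
    return PcaResult(scores, loadings, evf)


def sample_correlation(matrix: pd.DataFrame, min_shared: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation between samples.

    Pairs sharing fewer than ``min_shared`` observed features get NaN.
    Returns (correlation matrix, shared-observation counts).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = matrix.to_numpy()
    runs = list(matrix.columns)
    n = len(runs)
    corr = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    finite = np.isfinite(X)
    for i in range(n):
        corr[i, i] = 1.0
        counts[i, i] = int(finite[:, i].sum())
        for j in range(i + 1, n):
            shared = finite[:, i] & finite[:, j]
            counts[i, j] = counts[j, i] = int(shared.sum())
            if counts[i, j] >= min_shared:
                xi, xj = X[shared, i], X[shared, j]
                if xi.std() > 0 and xj.std() > 0:
                    corr[i, j] = corr[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return (
        pd.DataFrame(corr, index=runs, columns=runs),
        pd.DataFrame(counts, index=runs, columns=runs),
    )


def cv_summary(linear_matrix: pd.DataFrame, design: StudyDesign) -> tuple[pd.DataFrame, pd.Series]:
    """Per-condition coefficient of variation (SD/mean, linear scale).

    Features with <2 observed replicates in a condition are excluded from
    that condition.  Returns the per-feature CV table and the median CV
    per condition.
    """
    cv = pd.DataFrame(index=linear_matrix.index)
    for cond in design.conditions:
        runs = design.runs_of(cond)
        sub = linear_matrix[runs]
        n_obs = sub.notna().sum(axis=1)
        sd = sub.std(axis=1, ddof=1)
        mean = sub.mean(axis=1)
        col = (sd / mean).where(n_obs >= 2)
        cv[cond] = col
    medians = cv.median(axis=0, skipna=True)
    medians.name = "median_cv"
    return cv, medians


def on_off_analysis(
    table: PrecursorTable,
    design: StudyDesign,
    min_on_fraction: float = 1.0,
    max_off_fraction: float = 0.0,
) -> pd.DataFrame:
    """Presence/absence calls per protein and comparison.

    A protein is detected in a run when >=1 of its precursors has an
    observed quantity there.  Per comparison (A vs B): ON_in_A when
    fraction_A >= min_on_fraction and fraction_B <= max_off_fraction,
    symmetrically ON_in_B; otherwise none.
    """
    if not min_on_fraction > max_off_fraction:
        raise ValueError("min_on_fraction must exceed max_off_fraction")
    obs = table.df[table.df["quantity"].notna()]
    detected = obs.groupby(["protein_group", "run_id"]).size().unstack(fill_value=0) > 0
    detected = detected.reindex(columns=design.run_ids, fill_value=False)
    all_proteins = pd.Index(sorted(table.df["protein_group"].unique()), name="protein_group")
    detected = detected.reindex(index=all_proteins, fill_value=False)

    out = pd.DataFrame(index=all_proteins)
    for cond in design.conditions:
        runs = design.runs_of(cond)
        out[f"fraction[{cond}]"] = detected[runs].mean(axis=1)
    for num, den in design.comparisons:
        fa = out[f"fraction[{num}]"]
        fb = out[f"fraction[{den}]"]
        call = np.where(
            (fa >= min_on_fraction) & (fb <= max_off_fraction),
            "ON_in_A",
            np.where((fb >= min_on_fraction) & (fa <= max_off_fraction), "ON_in_B", "none"),
        )
        out[f"call[{num}_vs_{den}]"] = call
    return out.reset_index()
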