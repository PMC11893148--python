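"""Peptide-centric differential statistics with ROPECA-style aggregation.

Per comparison, every precursor with >=2 observed replicates in both
conditions gets a two-sample t statistic (pooled variance by default,
optionally Welch), optionally moderated by empirical-Bayes variance
shrinkage toward a scaled inverse-chi-square prior fitted by method of
moments.  Per protein, the median peptide log2-ratio carries the effect
and the median peptide p-value is converted to a protein-level
significance through the order-statistic null distribution of the median
of n iid Uniform(0,1) variables (Beta CDF for odd n; a cached Monte-Carlo
table for even n).  BH adjustment runs across proteins within each
comparison.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .datamodel import PeptideMatrix, ProteinQuantTable, StudyDesign

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peptide-level tests

def peptide_t_test(
    matrix: PeptideMatrix,
    comparison: tuple[str, str],
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t per precursor for one (numerator, denominator) comparison.

    Complete-case within the comparison: a precursor needs >=2 finite
    values in each condition, otherwise it is skipped.  Returns a frame
    with log2_ratio (mean_num - mean_den), t, df, p, group sizes and the
    residual variance / SE structure needed for moderation.
    """
    num, den = comparison
    runs_a = matrix.design.runs_of(num)
    runs_b = matrix.design.runs_of(den)
    a = matrix.values[runs_a].to_numpy()
    b = matrix.values[runs_b].to_numpy()
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    ok = (n_a >= 2) & (n_b >= 2)

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    ratio = mean_a - mean_b

    if welch:
        se2 = var_a / n_a + var_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
        s2 = se2  # Welch: moderation not supported on heterogeneous structure
        se_struct = np.ones_like(se2)
        se = np.sqrt(se2)
    else:
        # batch/covariate adjustment consumed df_penalty residual degrees of
        # freedom per row; the pooled sum of squares is spread over the
        # remaining df so the variance estimate stays unbiased
        df = n_a + n_b - 2.0 - matrix.df_penalty
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            se_struct = 1.0 / n_a + 1.0 / n_b
            se = np.sqrt(s2 * se_struct)
        ok &= df >= 1

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, ratio / se, np.where(ratio == 0, 0.0, np.inf * np.sign(ratio)))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where((se == 0) & (ratio == 0), 1.0, p)

    out = pd.DataFrame(
        {
            "precursor_id": matrix.values.index,
            "protein_group": matrix.row_meta["protein_group"].to_numpy(),
            "log2_ratio": ratio,
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "n_A": n_a,
            "n_B": n_b,
            "s2": s2,
            "se_structure": se_struct,
        }
    )
    skipped = int((~ok).sum())
    if skipped:
        logger.info("comparison %s vs %s: %d precursors skipped (<2 values per group)", num, den, skipped)
    return out.loc[ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square prior for peptide residual variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from observed residual variances.

    Under the prior, log s^2 equals log s0^2 plus a log-F(df, d0) draw;
    matching mean and variance of log s^2 against digamma/trigamma
    identities yields the prior parameters.  If the observed spread does
    not exceed the theoretical spread at d0 = inf, d0 = inf is returned.
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    keep = np.isfinite(s2) & (df >= 1)
    s2, df = s2[keep], df[keep]
    if s2.size < 10:
        raise ValueError(f"need >=10 variances with df >= 1, got {s2.size}")
    if np.all(s2 == 0):
        raise ValueError("degenerate variances: all zero")
    positive = s2 > 0
    if not positive.all():
        logger.warning("%d zero variances excluded from moderation fit", int((~positive).sum()))
        s2, df = s2[positive], df[positive]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return ModerationParams(np.inf, float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationParams(float(d0), float(s0_sq))


def moderated_t(peptide_stats: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Replace each peptide's variance by the posterior shrunken variance.

    s~^2 = (d0 s0^2 + df s^2) / (d0 + df); the t statistic is recomputed
    with the same SE structure and referred to a t distribution with
    d0 + df degrees of freedom (normal reference when d0 = inf).  d0 = 0
    reproduces the ordinary test exactly.
    """
    out = peptide_stats.copy()
    s2 = out["s2"].to_numpy(float)
    df = out["df"].to_numpy(float)
    if np.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        df_total = params.d0 + df
    se = np.sqrt(s2_post * out["se_structure"].to_numpy(float))
    ratio = out["log2_ratio"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, ratio / se, np.where(ratio == 0, 0.0, np.inf * np.sign(ratio)))
    finite_df = np.isfinite(df_total)
    p = np.where(
        finite_df,
        2.0 * sps.t.sf(np.abs(t), np.where(finite_df, df_total, 1.0)),
        2.0 * sps.norm.sf(np.abs(t)),
    )
    p = np.where((se == 0) & (ratio == 0), 1.0, p)
    out["t_statistic"] = t
    out["df"] = df_total
    out["p_value"] = p
    out["s2_posterior"] = s2_post
    return out


# ---------------------------------------------------------------------------
# ROPECA aggregation: null distribution of the median of n uniforms

_MEDIAN_NULL_CACHE: dict[int, np.ndarray] = {}
_MC_DRAWS = 1_000_000


def _even_median_table(n: int) -> np.ndarray:
    """Sorted Monte-Carlo draws of the median of n iid Uniform(0,1), even n.

    Deterministically seeded per n; the empirical CDF of this table serves
    as the null distribution (tolerance ~1e-3 at 1e6 draws).
    """
    if n not in _MEDIAN_NULL_CACHE:
        rng = np.random.default_rng(987_654 + n)
        u = rng.random((_MC_DRAWS, n))
        k = n // 2
        part = np.partition(u, [k - 1, k], axis=1)
        med = 0.5 * (part[:, k - 1] + part[:, k])
        _MEDIAN_NULL_CACHE[n] = np.sort(med)
    return _MEDIAN_NULL_CACHE[n]


def median_p_significance(median_p: float, n: int) -> float:
    """P(median of n iid Uniform(0,1) <= median_p).

    Odd n: Beta(k, n-k+1) CDF at median_p with k = (n+1)/2 (exact).
    Even n: empirical CDF of a cached Monte-Carlo table of the average of
    the two central order statistics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not np.isfinite(median_p):
        return np.nan
    median_p = float(np.clip(median_p, 0.0, 1.0))
    if n % 2 == 1:
        k = (n + 1) // 2
        return float(sps.beta.cdf(median_p, k, n - k + 1))
    table = _even_median_table(n)
    return float(np.searchsorted(table, median_p, side="right") / table.size)


def ropeca_aggregate(peptide_stats: pd.DataFrame) -> pd.DataFrame:
    """Aggregate peptide statistics to protein level, PECA style.

    Per protein: median peptide log2-ratio, median peptide p-value, and
    the order-statistic protein significance of the median p.
    """
    if peptide_stats.empty:
        return pd.DataFrame(
            columns=["protein_group", "n_peptides_tested", "median_log2_ratio", "median_p", "protein_p"]
        )
    grouped = peptide_stats.groupby("protein_group", sort=True)
    agg = grouped.agg(
        n_peptides_tested=("p_value", "size"),
        median_log2_ratio=("log2_ratio", "median"),
        median_p=("p_value", "median"),
    ).reset_index()
    agg["protein_p"] = [
        median_p_significance(mp, int(n))
        for mp, n in zip(agg["median_p"], agg["n_peptides_tested"])
    ]
    return agg


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def protein_effect_size(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Cohen's d between two groups of per-sample protein log2 values.

    Returns NaN when either group has <2 finite values; +/-inf when the
    pooled SD is zero but the means differ; 0 when both are identical.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    diff = a.mean() - b.mean()
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf * np.sign(diff)
    return float(diff / pooled)


# ---------------------------------------------------------------------------
# per-comparison driver

def run_comparison(
    matrix: PeptideMatrix,
    comparison: tuple[str, str],
    method: str = "ropeca",
    protein_table: ProteinQuantTable | None = None,
    decile_annotation: pd.DataFrame | None = None,
    welch: bool = False,
    peptide_stat_fn: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Full protein-level differential analysis for one comparison.

    ``method`` chooses the peptide-level statistic: "t" (plain two-sample
    t), "modt" or "ropeca" (empirical-Bayes moderated t; "ropeca" is the
    default alias).  Aggregation to protein level is always the PECA
    median-p order-statistic step.  ``peptide_stat_fn`` allows plugging a
    custom peptide statistic (takes and returns the peptide stats frame).
    Effect sizes are Cohen's d on the supplied protein profiles (MaxLFQ
    recommended).
    """
    if method not in {"ropeca", "modt", "t"}:
        raise ValueError(f"unknown statistics method {method!r}")
    pep = peptide_t_test(matrix, comparison, welch=welch)
    if method in {"ropeca", "modt"} and not pep.empty:
        if welch:
            raise ValueError("moderated t requires the pooled-variance test (welch=False)")
        params = estimate_moderation(pep["s2"].to_numpy(), pep["df"].to_numpy())
        pep = moderated_t(pep, params)
    if peptide_stat_fn is not None:
        pep = peptide_stat_fn(pep)
    prot = ropeca_aggregate(pep)
    if prot.empty:
        return prot
    prot["adj_p"] = bh_adjust(prot["protein_p"].to_numpy())

    num, den = comparison
    if protein_table is not None:
        log2_prof = protein_table.log2_values()
        runs_a = [r for r in matrix.design.runs_of(num) if r in log2_prof.columns]
        runs_b = [r for r in matrix.design.runs_of(den) if r in log2_prof.columns]
        effect = []
        for pg in prot["protein_group"]:
            if pg in log2_prof.index:
                effect.append(
                    protein_effect_size(
                        log2_prof.loc[pg, runs_a].to_numpy(), log2_prof.loc[pg, runs_b].to_numpy()
                    )
                )
            else:
                effect.append(np.nan)
        prot["effect_size"] = effect
    else:
        prot["effect_size"] = np.nan

    if decile_annotation is not None:
        dec_a = decile_annotation.get(f"decile[{num}]")
        dec_b = decile_annotation.get(f"decile[{den}]")
        prot["decile_A"] = dec_a.reindex(prot["protein_group"]).to_numpy() if dec_a is not None else pd.NA
        prot["decile_B"] = dec_b.reindex(prot["protein_group"]).to_numpy() if dec_b is not None else pd.NA
        code = decile_annotation.get(f"2d_code[{num}_vs_{den}]")
        prot["2d_code"] = code.reindex(prot["protein_group"]).to_numpy() if code is not None else ""
    prot.insert(0, "comparison", f"{num}_vs_{den}")
    return prot


def run_all_comparisons(
    matrix: PeptideMatrix,
    method: str = "ropeca",
    protein_table: ProteinQuantTable | None = None,
    decile_annotation: pd.DataFrame | None = None,
    welch: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """run_comparison for every comparison in the design (BH within each)."""
    return {
        cmp: run_comparison(matrix, cmp, method, protein_table, decile_annotation, welch)
        for cmp in matrix.design.comparisons
    }
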