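"""Protein-level quantification: iBAQ, Hi3/Top3 and MaxLFQ.

iBAQ divides a protein's summed linear intensity by its count of
theoretically observable tryptic peptides (in-silico digestion, cleavage
C-terminal of K/R except before P).  Hi3 averages the three most intense
precursors per sample.  MaxLFQ reconstructs a per-sample log2 profile from
medians of pairwise peptide log-ratios by least squares, anchored so the
profile's total linear-scale signal matches the observed total.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .datamodel import PeptideMatrix, ProteinQuantTable, StudyDesign

logger = logging.getLogger(__name__)

_CLEAVE_AFTER = frozenset("KR")


@dataclass(frozen=True)
class DigestParams:
    """In-silico trypsin digestion settings for iBAQ observable-peptide counting."""

    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def tryptic_fragments(sequence: str) -> list[str]:
    """Fully cleaved tryptic fragments: cut after K/R unless the next residue is P."""
    frags, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in _CLEAVE_AFTER and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            frags.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    return frags


def count_observable_peptides(
    sequence: str,
    min_len: int = 7,
    max_len: int = 30,
    missed_cleavages: int = 0,
) -> int:
    """Count distinct in-silico tryptic peptides with length in [min_len, max_len].

    With m missed cleavages, all concatenations of up to m+1 consecutive
    fully-cleaved fragments are candidate peptides; distinct sequences are
    counted once.
    """
    from .io_ingest import VALID_RESIDUES

    if not sequence:
        raise ValueError("empty protein sequence")
    sequence = sequence.upper()
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    DigestParams(min_len, max_len, missed_cleavages)
    frags = tryptic_fragments(sequence)
    peptides: set[str] = set()
    for i in range(len(frags)):
        pep = ""
        for j in range(i, min(i + missed_cleavages + 1, len(frags))):
            pep += frags[j]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
            if len(pep) > max_len:
                break
    return len(peptides)


def group_sequence(protein_group: str, sequences: dict[str, str]) -> tuple[str | None, bool]:
    """Resolve a (possibly multi-accession) protein group to one sequence.

    Multi-accession groups use the longest member sequence found in the
    FASTA; the second return value flags that a choice was made.
    """
    accessions = [a.strip() for a in protein_group.split(";") if a.strip()]
    present = [a for a in accessions if a in sequences]
    if not present:
        return None, False
    chosen = max(present, key=lambda a: len(sequences[a]))
    return sequences[chosen], len(accessions) > 1


def build_digest_index(
    protein_groups: list[str], sequences: dict[str, str], params: DigestParams = DigestParams()
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Observable-peptide counts per protein group, with per-group flags."""
    counts, flags = {}, {}
    for pg in protein_groups:
        seq, multi = group_sequence(pg, sequences)
        pg_flags = []
        if multi:
            pg_flags.append("multi_accession_longest_used")
        if seq is None:
            counts[pg] = 0
            pg_flags.append("no_fasta_sequence")
        else:
            counts[pg] = count_observable_peptides(
                seq, params.min_len, params.max_len, params.missed_cleavages
            )
            if counts[pg] == 0:
                pg_flags.append("no_theoretical_peptides")
        if pg_flags:
            flags[pg] = pg_flags
    return pd.Series(counts, name="observable_peptides"), flags


def ibaq(
    matrix: PeptideMatrix, sequences: dict[str, str], params: DigestParams = DigestParams()
) -> ProteinQuantTable:
    """iBAQ = summed linear precursor intensity / observable tryptic peptide count."""
    linear = matrix.linear()
    groups = matrix.row_meta["protein_group"]
    sums = linear.groupby(groups).sum(min_count=1)
    n_pep = matrix.values.notna().any(axis=1).groupby(groups).sum().astype(int)
    obs_counts, flags = build_digest_index(list(sums.index), sequences, params)
    divisor = obs_counts.reindex(sums.index).astype(float)
    values = sums.div(divisor.where(divisor > 0), axis=0)
    return ProteinQuantTable("iBAQ", values, n_pep.reindex(sums.index), flags)


def top3(matrix: PeptideMatrix) -> ProteinQuantTable:
    """Hi3: per sample, mean of the protein's 3 largest linear precursor intensities."""
    linear = matrix.linear().to_numpy()
    groups = matrix.row_meta["protein_group"].to_numpy()
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    uniq, starts = np.unique(sorted_groups, return_index=True)
    bounds = np.append(starts, len(sorted_groups))
    out = np.full((len(uniq), linear.shape[1]), np.nan)
    n_pep = np.zeros(len(uniq), dtype=int)
    flags: dict[str, list[str]] = {}
    for g in range(len(uniq)):
        block = linear[order[bounds[g] : bounds[g + 1]]]
        n_pep[g] = int(np.isfinite(block).any(axis=1).sum())
        min_used = 3
        for s in range(block.shape[1]):
            col = block[:, s]
            vals = col[np.isfinite(col)]
            if vals.size == 0:
                continue
            k = min(3, vals.size)
            min_used = min(min_used, k)
            out[g, s] = np.mean(np.sort(vals)[-k:])
        if 0 < min_used < 3:
            flags[uniq[g]] = [f"n_used={min_used}"]
    values = pd.DataFrame(out, index=pd.Index(uniq, name="protein_group"), columns=matrix.values.columns)
    return ProteinQuantTable("Hi3", values, pd.Series(n_pep, index=values.index), flags)


def maxlfq_profile(
    log2_mat: np.ndarray, min_peptides_pair: int = 2
) -> tuple[np.ndarray, list[str]]:
    """MaxLFQ log2 profile for one protein from a peptide x sample log2 matrix.

    Pairwise sample log-ratios are the medians over peptides observed in
    both samples (requiring >= min_peptides_pair shared peptides); the
    profile solves the least-squares system p_i - p_j ~ r_ij per connected
    component, with the gauge fixed by matching each component's summed
    linear-scale signal to the observed summed intensity.  Samples without
    data stay NaN.
    """
    mat = np.asarray(log2_mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 2:
        raise ValueError("need a peptide x sample matrix with >=1 peptide and >=2 samples")
    obs = np.isfinite(mat)
    n_samples = mat.shape[1]
    has_data = obs.any(axis=0)
    flags: list[str] = []

    pairs: list[tuple[int, int, float]] = []
    for i in range(n_samples):
        if not has_data[i]:
            continue
        for j in range(i + 1, n_samples):
            if not has_data[j]:
                continue
            common = obs[:, i] & obs[:, j]
            if int(common.sum()) >= min_peptides_pair:
                pairs.append((i, j, float(np.median(mat[common, i] - mat[common, j]))))

    col_totals = np.where(has_data, np.nansum(np.power(2.0, mat), axis=0), 0.0)

    profile = np.full(n_samples, np.nan)
    if not pairs:
        if int(has_data.sum()) > 1:
            flags.append("maxlfq_fallback")
        profile[has_data] = np.log2(col_totals[has_data])
        return profile, flags

    adjacency = np.zeros((n_samples, n_samples))
    A = np.zeros((n_samples, n_samples))
    b = np.zeros(n_samples)
    for i, j, r in pairs:
        adjacency[i, j] = adjacency[j, i] = 1
        A[i, i] += 1
        A[j, j] += 1
        A[i, j] -= 1
        A[j, i] -= 1
        b[i] += r
        b[j] -= r

    n_comp, labels = connected_components(adjacency, directed=False)
    for comp in range(n_comp):
        members = np.where((labels == comp) & has_data)[0]
        if members.size == 0:
            continue
        if members.size == 1:
            # isolated sample: anchored directly to its own summed signal
            profile[members[0]] = np.log2(col_totals[members[0]])
            continue
        sub = A[np.ix_(members, members)]
        p, *_ = np.linalg.lstsq(sub, b[members], rcond=None)
        total_obs = col_totals[members].sum()
        shift = np.log2(total_obs / np.power(2.0, p).sum())
        profile[members] = p + shift
    if n_comp > 1 and has_data.sum() > 1:
        flags.append("disconnected_components")
    return profile, flags


def maxlfq(matrix: PeptideMatrix, min_peptides_pair: int = 2) -> ProteinQuantTable:
    """MaxLFQ profiles (log2 scale) for every protein group in the matrix."""
    groups = matrix.row_meta["protein_group"].to_numpy()
    values_arr = matrix.values.to_numpy()
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    uniq, starts = np.unique(sorted_groups, return_index=True)
    bounds = np.append(starts, len(sorted_groups))
    out = np.full((len(uniq), values_arr.shape[1]), np.nan)
    n_pep = np.zeros(len(uniq), dtype=int)
    flags: dict[str, list[str]] = {}
    for g in range(len(uniq)):
        block = values_arr[order[bounds[g] : bounds[g + 1]]]
        n_pep[g] = int(np.isfinite(block).any(axis=1).sum())
        if block.shape[1] < 2:
            out[g] = block[0] if block.shape[0] == 1 else np.nan
            continue
        profile, f = maxlfq_profile(block, min_peptides_pair)
        out[g] = profile
        if f:
            flags[uniq[g]] = f
    values = pd.DataFrame(out, index=pd.Index(uniq, name="protein_group"), columns=matrix.values.columns)
    return ProteinQuantTable("MaxLFQ", values, pd.Series(n_pep, index=values.index), flags)


def assign_ibaq_deciles(
    ibaq_table: ProteinQuantTable, design: StudyDesign, n_bins: int = 10
) -> pd.DataFrame:
    """Per-condition abundance deciles (1..10, 10 = most abundant) from mean iBAQ.

    Per condition, each protein's iBAQ values are averaged over that
    condition's samples (missing ignored), ranked with average ties, and
    binned into empirical deciles; per comparison a 2D code
    "decile_num|decile_den" is emitted for the table color map.
    """
    if ibaq_table.method != "iBAQ":
        raise ValueError("decile annotation requires the iBAQ table")
    deciles = pd.DataFrame(index=ibaq_table.values.index)
    for cond in design.conditions:
        runs = design.runs_of(cond)
        mean_ibaq = ibaq_table.values[runs].mean(axis=1, skipna=True)
        if mean_ibaq.notna().sum() == 0:
            raise ValueError(f"condition {cond!r} has no iBAQ values")
        if mean_ibaq.notna().sum() < n_bins:
            logger.warning(
                "condition %r has %d proteins with iBAQ (< %d); decile bins collapse",
                cond, int(mean_ibaq.notna().sum()), n_bins,
            )
        rank = mean_ibaq.rank(method="average", na_option="keep")
        n = rank.notna().sum()
        dec = np.ceil(rank * n_bins / n).clip(1, n_bins)
        deciles[f"decile[{cond}]"] = dec.astype("Int64")
    for num, den in design.comparisons:
        a, b = deciles[f"decile[{num}]"], deciles[f"decile[{den}]"]
        deciles[f"2d_code[{num}_vs_{den}]"] = [
            ("NA" if pd.isna(x) else str(int(x))) + "|" + ("NA" if pd.isna(y) else str(int(y)))
            for x, y in zip(a, b)
        ]
    return deciles


def quantify(
    matrix: PeptideMatrix,
    sequences: dict[str, str] | None = None,
    methods: tuple[str, ...] = ("iBAQ", "Hi3", "MaxLFQ"),
    digest_params: DigestParams = DigestParams(),
    min_peptides_pair: int = 2,
) -> dict[str, ProteinQuantTable]:
    """Run the requested quantification methods over one peptide matrix."""
    results: dict[str, ProteinQuantTable] = {}
    for method in methods:
        if method == "iBAQ":
            if sequences is None:
                raise ValueError("iBAQ requested but no FASTA sequences supplied")
            results["iBAQ"] = ibaq(matrix, sequences, digest_params)
        elif method == "Hi3":
            results["Hi3"] = top3(matrix)
        elif method == "MaxLFQ":
            results["MaxLFQ"] = maxlfq(matrix, min_peptides_pair)
        else:
            raise ValueError(f"unknown quantification method {method!r}")
    return results
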