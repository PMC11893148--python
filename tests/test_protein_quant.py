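import numpy as np
import pandas as pd
import pytest

from diaquant import protein_quant as pq
from diaquant.datamodel import PeptideMatrix, ProteinQuantTable

from conftest import make_design


# ---------------------------------------------------------------------------
# independent oracles

def digest_oracle(seq, min_len, max_len, mc):
    """Brute-force digestion: enumerate all substrings whose internal cut
    sites are exactly a run of <= mc skipped cleavage sites."""
    sites = [0]
    for i in range(len(seq)):
        if seq[i] in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            if i + 1 < len(seq):
                sites.append(i + 1)
    sites.append(len(seq))
    sites = sorted(set(sites))
    peptides = set()
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + mc + 2, len(sites))):
            pep = seq[sites[a] : sites[b]]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return len(peptides)


def maxlfq_dense_oracle(mat, min_pairs=1):
    """Dense least squares on the full pair-difference system; returns a
    profile with mean zero over samples with data (gauge-free comparison)."""
    obs = np.isfinite(mat)
    S = mat.shape[1]
    rows, rhs = [], []
    for i in range(S):
        for j in range(i + 1, S):
            common = obs[:, i] & obs[:, j]
            if common.sum() >= min_pairs:
                row = np.zeros(S)
                row[i], row[j] = 1.0, -1.0
                rows.append(row)
                rhs.append(np.median(mat[common, i] - mat[common, j]))
    A = np.array(rows)
    p, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
    return p - p.mean()


def build_matrix(values, proteins, design):
    idx = pd.Index([f"pep{i}" for i in range(values.shape[0])], name="precursor_id")
    df = pd.DataFrame(values, index=idx, columns=design.run_ids)
    meta = pd.DataFrame(
        {"protein_group": proteins, "stripped_sequence": [f"SEQ{i}K" for i in range(len(idx))]},
        index=idx,
    )
    return PeptideMatrix(df, meta, design)


# ---------------------------------------------------------------------------
# digestion

class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACDEFGH", 1),  # single fragment of length 7
            ("ACD", 0),  # too short
            ("AKPGGGGGG", 1),  # K-P suppresses cleavage: one length-9 fragment
        ],
    )
    def test_known_counts(self, seq, expected):
        assert pq.count_observable_peptides(seq, 7, 30, 0) == expected

    def test_missed_cleavage_concatenation(self):
        # fragments: ABCDEFK | GHILMNK -> mc=1 adds the 14-mer
        seq = "ACDEFGKGHILMNK"
        assert pq.count_observable_peptides(seq, 7, 30, 0) == 2
        assert pq.count_observable_peptides(seq, 7, 30, 1) == 3

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            pq.count_observable_peptides("ACDJ", 7, 30, 0)

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(99)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        # bias toward K/R/P so suppression and short fragments are common
        probs = np.ones(20)
        for aa in "KRP":
            probs[list(alphabet).index(aa)] = 4.0
        probs /= probs.sum()
        for _ in range(1000):
            n = int(rng.integers(5, 80))
            seq = "".join(rng.choice(alphabet, size=n, p=probs))
            mc = int(rng.integers(0, 3))
            mine = pq.count_observable_peptides(seq, 7, 30, mc)
            assert mine == digest_oracle(seq, 7, 30, mc), (seq, mc)

    def test_deterministic(self):
        seq = "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGE"
        assert pq.count_observable_peptides(seq) == pq.count_observable_peptides(seq)


# ---------------------------------------------------------------------------
# iBAQ

class TestIbaq:
    def make(self, design, qty_rows, proteins):
        return build_matrix(np.log2(np.asarray(qty_rows, float)), proteins, design)

    def test_sum_divided_by_observable_count(self):
        design = make_design(["A"], 1)
        # protein with 2 observed precursors 600+400 and observable count 4 -> 250
        m = self.make(design, [[600.0], [400.0]], ["P1", "P1"])
        # sequence with exactly 4 observable tryptic peptides
        seq = "AAAAAAK" + "CCCCCCK" + "DDDDDDK" + "EEEEEEK"
        assert pq.count_observable_peptides(seq) == 4
        out = pq.ibaq(m, {"P1": seq})
        assert out.values.iloc[0, 0] == pytest.approx(250.0)
        assert out.n_peptides["P1"] == 2

    def test_observable_count_one_is_identity(self):
        design = make_design(["A"], 1)
        m = self.make(design, [[1000.0]], ["P1"])
        out = pq.ibaq(m, {"P1": "AAAAAAK"})
        assert out.values.iloc[0, 0] == pytest.approx(1000.0)

    def test_no_theoretical_peptides_flagged_missing(self):
        design = make_design(["A"], 1)
        m = self.make(design, [[1000.0]], ["P1"])
        out = pq.ibaq(m, {"P1": "ACD"})  # too short for any observable peptide
        assert np.isnan(out.values.iloc[0, 0])
        assert "no_theoretical_peptides" in out.flags["P1"]

    def test_missing_sample_stays_missing(self):
        design = make_design(["A"], 2)
        vals = np.array([[np.log2(1000.0), np.nan]])
        m = build_matrix(vals, ["P1"], design)
        out = pq.ibaq(m, {"P1": "AAAAAAK"})
        assert np.isnan(out.values.iloc[0, 1])

    def test_row_order_invariance(self):
        design = make_design(["A"], 1)
        seq = {"P1": "AAAAAAKCCCCCCK"}
        a = pq.ibaq(self.make(design, [[600.0], [400.0]], ["P1", "P1"]), seq)
        b = pq.ibaq(self.make(design, [[400.0], [600.0]], ["P1", "P1"]), seq)
        assert a.values.iloc[0, 0] == b.values.iloc[0, 0]


# ---------------------------------------------------------------------------
# Hi3

class TestTop3:
    def test_mean_of_three_largest(self):
        design = make_design(["A"], 1)
        m = build_matrix(np.log2([[10.0], [20.0], [30.0], [40.0]]), ["P1"] * 4, design)
        out = pq.top3(m)
        assert out.values.iloc[0, 0] == pytest.approx(30.0)

    def test_fewer_than_three_flagged(self):
        design = make_design(["A"], 1)
        m = build_matrix(np.log2([[50.0]]), ["P1"], design)
        out = pq.top3(m)
        assert out.values.iloc[0, 0] == pytest.approx(50.0)
        assert out.flags["P1"] == ["n_used=1"]

    def test_tie_invariance(self):
        design = make_design(["A"], 1)
        m = build_matrix(np.log2([[30.0]] * 4), ["P1"] * 4, design)
        assert pq.top3(m).values.iloc[0, 0] == pytest.approx(30.0)

    def test_monotone_in_selected_intensity(self):
        design = make_design(["A"], 1)
        base = pq.top3(build_matrix(np.log2([[10.0], [20.0], [30.0], [40.0]]), ["P1"] * 4, design))
        more = pq.top3(build_matrix(np.log2([[10.0], [20.0], [30.0], [80.0]]), ["P1"] * 4, design))
        assert more.values.iloc[0, 0] > base.values.iloc[0, 0]


# ---------------------------------------------------------------------------
# MaxLFQ

class TestMaxLFQ:
    def test_consistent_unit_ratio(self):
        mat = np.array([[10.0, 9.0], [12.0, 11.0], [8.5, 7.5]])
        profile, flags = pq.maxlfq_profile(mat)
        assert profile[0] - profile[1] == pytest.approx(1.0, abs=1e-10)
        assert flags == []

    def test_single_peptide_equals_its_values(self):
        mat = np.array([[10.0, 11.0, 12.5]])
        profile, flags = pq.maxlfq_profile(mat, min_peptides_pair=1)
        assert np.allclose(profile - profile[0], mat[0] - mat[0, 0], atol=1e-10)

    def test_gauge_matches_total_signal(self):
        mat = np.array([[10.0, 9.0], [12.0, 11.0]])
        profile, _ = pq.maxlfq_profile(mat)
        assert np.power(2.0, profile).sum() == pytest.approx(np.power(2.0, mat).sum())

    def test_inconsistent_ratios_match_dense_oracle(self):
        rng = np.random.default_rng(17)
        mat = rng.normal(12, 1, size=(3, 3))
        profile, _ = pq.maxlfq_profile(mat, min_peptides_pair=2)
        oracle = maxlfq_dense_oracle(mat, min_pairs=2)
        assert np.allclose(profile - profile.mean(), oracle, atol=1e-8)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_pep = int(rng.integers(1, 11))
            n_s = int(rng.integers(2, 7))
            mat = rng.normal(12, 2, size=(n_pep, n_s))
            drop = rng.random(mat.shape) < 0.2
            mat[drop] = np.nan
            obs = np.isfinite(mat)
            profile, flags = pq.maxlfq_profile(mat, min_peptides_pair=1)
            if "maxlfq_fallback" in flags or "disconnected_components" in flags:
                continue
            has = obs.any(axis=0)
            if has.sum() < 2:
                continue
            oracle = maxlfq_dense_oracle(mat, min_pairs=1)
            mine = profile[has] - profile[has].mean()
            assert np.allclose(mine, oracle[has] - oracle[has].mean(), atol=1e-8)

    def test_shift_equivariance_modulo_gauge(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(12, 1, size=(5, 4))
        p0, _ = pq.maxlfq_profile(mat)
        shifted = mat.copy()
        shifted[:, 2] += 1.5
        p1, _ = pq.maxlfq_profile(shifted)
        d0 = p0 - p0[0]
        d1 = p1 - p1[0]
        expect = d0.copy()
        expect[2] += 1.5
        assert np.allclose(d1, expect, atol=1e-8)

    def test_no_valid_pair_falls_back_to_sums(self):
        mat = np.array([[10.0, np.nan], [np.nan, 11.0]])
        profile, flags = pq.maxlfq_profile(mat, min_peptides_pair=2)
        assert "maxlfq_fallback" in flags
        assert np.allclose(profile, [10.0, 11.0])

    def test_sample_without_data_is_missing(self):
        mat = np.array([[10.0, 11.0, np.nan], [9.0, 10.0, np.nan]])
        profile, _ = pq.maxlfq_profile(mat)
        assert np.isnan(profile[2])

    def test_noise_free_recovery_of_pairwise_differences(self):
        rng = np.random.default_rng(12)
        true = rng.normal(12, 1, 5)
        offsets = rng.normal(0, 2, 7)
        mat = true[None, :] + offsets[:, None]
        profile, _ = pq.maxlfq_profile(mat)
        assert np.allclose(profile - profile[0], true - true[0], atol=1e-8)


# ---------------------------------------------------------------------------
# iBAQ deciles

def make_ibaq_table(values, design):
    idx = pd.Index([f"P{i:03d}" for i in range(len(values))], name="protein_group")
    df = pd.DataFrame(values, index=idx, columns=design.run_ids)
    return ProteinQuantTable("iBAQ", df, pd.Series(1, index=idx))


class TestDeciles:
    def test_ten_increasing_proteins_map_to_1_to_10(self):
        design = make_design(["A", "B"], 1)
        vals = np.column_stack([np.arange(1.0, 11.0)] * 2)
        ann = pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
        assert list(ann["decile[A]"]) == list(range(1, 11))

    def test_all_equal_share_one_decile(self):
        design = make_design(["A"], 1, comparisons=[])
        vals = np.full((10, 1), 5.0)
        ann = pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
        assert ann["decile[A]"].nunique() == 1

    def test_matches_sort_and_bin_oracle_20_proteins(self):
        design = make_design(["A"], 1, comparisons=[])
        rng = np.random.default_rng(6)
        vals = rng.lognormal(10, 2, size=(20, 1))
        ann = pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
        # oracle: average-rank then ceil(rank/n*10)
        order = pd.Series(vals[:, 0]).rank(method="average")
        expected = np.ceil(order * 10 / 20).clip(1, 10).astype(int)
        assert list(ann["decile[A]"]) == list(expected)

    def test_invariant_under_monotone_transform(self):
        design = make_design(["A"], 1, comparisons=[])
        rng = np.random.default_rng(7)
        vals = rng.lognormal(10, 2, size=(25, 1))
        a = pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
        b = pq.assign_ibaq_deciles(make_ibaq_table(np.sqrt(vals), design), design)
        assert list(a["decile[A]"]) == list(b["decile[A]"])

    def test_2d_code_format(self):
        design = make_design(["A", "B"], 1)
        vals = np.column_stack([np.arange(1.0, 11.0), np.arange(10.0, 0.0, -1.0)])
        ann = pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
        assert ann.loc["P000", "2d_code[B_vs_A]"] == "10|1"

    def test_empty_condition_errors(self):
        design = make_design(["A", "B"], 1)
        vals = np.column_stack([np.arange(1.0, 11.0), np.full(10, np.nan)])
        with pytest.raises(ValueError, match="'B'"):
            pq.assign_ibaq_deciles(make_ibaq_table(vals, design), design)
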