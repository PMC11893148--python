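# Methods

This note documents the models, defaults and numerical choices behind
`diaquant`, and what the synthetic-data tests do and do not establish about
real data.

## Input model and preprocessing

The pipeline's currency is the long-format precursor table: one row per
(precursor, run) with a linear-scale quantity and identification q-values
at precursor and protein-group level. The quantification unit throughout is
the precursor (modified sequence + charge); aggregation to stripped
peptides happens only in identification counting. Quantities ≤ 0 or
unparseable are treated as missing; duplicate (precursor, run) rows
collapse to the lowest precursor q-value.

**q-value filtering** (defaults 0.01/0.01) censors the quantity but keeps
the row, so identification summaries remain computable before and after
filtering from one table. **Oxidized-Met removal** drops a precursor in all
runs when its modified sequence contains any configured tag substring
(defaults cover the common report dialects). **Condition-wise filtering**
keeps a precursor iff its observed fraction reaches `min_fraction`
(default 0.5) in at least one condition; the kept set is monotone in the
threshold.

**Normalization** is median-centering on the log2 scale: each sample's
median is shifted to the median of all sample medians. It is deterministic
and idempotent, and removes constant sample shifts exactly. Its assumption
is the usual one: most features are not changing, or regulation is roughly
balanced between directions. When a large fraction of proteins is regulated
in one direction, about `fraction × FC` of the signal is absorbed into the
sample medians, biasing ratios toward zero and shifting null proteins
off-center. The `--no-normalize` path exists for reports already normalized
upstream, and protein-level fold-change recovery is therefore measured on
un-normalized data in the acceptance checks (the generator simulates no
loading differences).

**Batch/covariate adjustment** fits, per precursor row, ordinary least
squares of log2 intensity on condition + batch + centered covariates over
the observed cells, and subtracts only the batch/covariate contributions —
condition effects cannot be erased by construction. A rank-deficient design
(batch confounded with condition) is a hard error. Rows with too few
observations pass through unadjusted and are flagged. Because the
adjustment removes noise along the nuisance directions, the matrix records
the number of nuisance parameters as a degrees-of-freedom penalty, and the
downstream pooled t-test spreads the pooled sum of squares over
`n_A + n_B − 2 − penalty` degrees of freedom. With complete data and a
two-condition design this is the exact residual df; with row-specific
missingness it is an approximation (slightly conservative when nuisance
coefficients are estimated on fewer cells). Missing values are never
imputed anywhere; all downstream statistics are complete-case per
comparison.

## Protein quantification

**In-silico digestion** cleaves C-terminal of K/R except before P; with
`m` missed cleavages every concatenation of up to `m+1` consecutive
fragments is a candidate, and distinct sequences with length in
[`min_len`, `max_len`] are counted. Defaults 7–30, 0 missed cleavages —
the classical observable-peptide window for iBAQ. **iBAQ** divides the
protein's summed linear precursor intensity per sample by that count;
samples with no observed precursor stay missing. Multi-accession protein
groups are digested on the longest member sequence present in the FASTA
and flagged.

**Hi3** is the per-sample mean of the three largest precursor intensities
(fewer available → mean of those, flagged `n_used=k`), computed on linear
values back-transformed from the normalized log2 matrix so normalization
carries over.

**MaxLFQ** forms, for every sample pair sharing at least
`min_peptides_pair` (default 2) peptides, the median of the pairwise log2
differences, then solves the least-squares system `p_i − p_j ≈ r_ij` via
the normal equations (minimum-norm solution of the gauge-singular system).
Connected components of the pair graph are solved independently; within
each component the gauge is fixed by matching the profile's summed
linear-scale intensity to the observed summed intensity, which preserves
the ratio structure and puts the profile on a meaningful abundance scale.
Proteins with data but no valid pair fall back to per-sample summed
intensity (`maxlfq_fallback` flag). Pairwise differences on noise-free data
are recovered to ≤1e-8, verified against a dense least-squares oracle.

**iBAQ deciles.** Per condition, protein mean iBAQ (missing ignored) is
ranked with average ties and binned into deciles `ceil(rank·10/n)` clipped
to 1..10 (10 = most abundant). The assignment is invariant under strictly
monotone transforms. Per comparison a `"d_A|d_B"` code drives the 2D table
color map (axis A → red channel, axis B → blue channel). Condition-mean
iBAQ was chosen over per-sample or median variants; the choice is
configurable in code.

## Differential statistics

Per comparison, each precursor with ≥2 finite values per condition gets a
pooled-variance two-sample t (Welch optional; pooled is the default because
variance moderation assumes a shared variance structure).

**Moderation.** Residual variances are modeled as draws from a scaled
inverse-χ²(d₀, s₀²) prior. On the log scale, `log s²` is `log s₀²` plus a
log-F(df, d₀) variable, so the prior is fitted by method of moments:
`e = log s² − ψ(df/2) + log(df/2)`; `var(e) − ψ'(df/2)` estimates
`ψ'(d₀/2)`, inverted by Newton iteration on the trigamma function, and the
mean of `e` gives `s₀²`. If the observed spread does not exceed the
theoretical sampling spread, `d₀ = ∞` (all variances equal `s₀²`, normal
reference). The posterior variance `(d₀s₀² + df·s²)/(d₀ + df)` feeds the
moderated t with `d₀ + df` degrees of freedom; `d₀ = 0` reproduces the
ordinary test exactly. Parameter recovery and null p-value uniformity are
verified by simulation.

**Protein aggregation (ROPECA-style).** The protein log2-ratio is the
median of its peptide ratios; the protein p-value is
`P(median of n iid U(0,1) ≤ median_p)`: for odd n the Beta(k, n−k+1) CDF
with `k = (n+1)/2` (exact); for even n the empirical CDF of a cached
Monte-Carlo table (10⁶ draws of the mean of the two central order
statistics, deterministic seed per n, accuracy ~1e-3). Because this is a
probability-integral transform of a continuous statistic, protein p-values
are uniform under the null when peptide p-values are, which is what the
type-I acceptance check measures. The reproducibility-bootstrap layer of
the original ROPECA family is replaced by the moderated t at peptide
level; the method knob (`ropeca` = moderated t + aggregation, `modt`
alias, `t` = plain t + aggregation) selects the peptide statistic, and a
hook accepts any custom peptide-statistic function. BH adjustment runs
across proteins within each comparison. Effect sizes are Cohen's d on
protein-level profiles (MaxLFQ by default).

## Synthetic data

The generator draws protein base levels ~ N(16, 2²) log2 units, peptide
ionisation offsets ~ N(0, 1.5²), replicate noise ~ N(0, 0.25²) by default —
magnitudes typical of DIA LFQ intensity data. Regulated proteins (count =
`floor(n·fraction)`, deterministic so truth counts are assertable) shift
all non-reference conditions by `true_log2_fc`. Optional additive batch
shifts, intensity-dependent logistic dropout (the dominant DIA missingness
mechanism), oxidized-Met precursor variants and q-values straddling the
0.01 threshold exercise every preprocessing path. Peptides are built from
an alphabet without K/R/P and terminated with K, and protein sequences are
their concatenation plus a sub-threshold decoy flank, so tryptic digestion
recovers exactly the generated peptides and iBAQ observable counts are
self-consistent. Generation is a pure function of (config, seed).

What the generator does **not** emulate: correlated peptide noise within a
protein, shared peptides between protein groups, retention-time-dependent
intensity drift, interference/co-fragmentation, missing-not-at-random
mechanisms beyond the intensity-logistic, or realistic sequence
composition. Passing tests therefore establish the internal correctness and
calibration of the algorithms under the stated model, not their behavior
under every real-data pathology.

## Problem sizes and numerical choices

The test suite and the acceptance script run studies of 40–2000 proteins
with 3–8 peptides each and 3 replicates per condition — large enough for
stable calibration estimates (binomial SE of a 0.05 rate at 2000 proteins
is ≈0.005) while keeping a full run in well under a minute. Tolerances:
normalization medians agree to 1e-9 and idempotence to 1e-12; MaxLFQ and
PCA match dense oracles to 1e-8; BH and the moderation limit cases to
1e-12; even-n median significance to ~1e-3 (Monte-Carlo table). Ties in
Hi3 and deciles are handled by average ranking; PCA uses a deterministic
sign convention (largest-magnitude loading entry positive) for bit-stable
outputs. Protein groups with no FASTA match or no theoretical peptides are
flagged and left missing rather than guessed.

## Known limitations

- Comparisons are pairwise two-condition; no omnibus or time-series
  models.
- The batch-adjustment df penalty is exact only for complete rows.
- MaxLFQ's gauge anchor (total observed intensity) is a convention;
  absolute levels are not calibrated quantities.
- Multi-accession groups use one representative sequence for digestion.
- The HTML report is static (embedded figures and tables, no widgets).
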