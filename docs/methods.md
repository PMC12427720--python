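# Methods

This note documents the models and estimators implemented in
`refstab`, the choices made where conventions diverge, and what the
synthetic-data generator does and does not emulate.

## Data model

A `CtMatrix` is a genes × samples table of quantification cycles with
per-sample annotations (organ, species, replicate).  Non-missing Cts
must fall in a plausibility window (default 5–45 cycles); blank,
`NA` and `Undetermined` cells are missing.  Technical replicates are
collapsed on the Ct scale *before* any transform (mean by default;
median available).  The aggregation statistic for replicate wells is
a convention, not a derivable fact — the mean is used because it is
what spreadsheet-based qPCR workflows almost universally do; a
replicate spread above 0.5 cycles raises a QC warning rather than an
error.  Genes missing in more than half the samples of a subset are
flagged and excluded from ranking by default: dispersion estimated
from fewer than a handful of points is noise.

Relative quantities are `Q(g, s) = E_g^(minCt_g − Ct(g, s))` with the
fold-per-cycle base `E_g ∈ (1, 2.2]`, default exactly 2.0 (the
2^−ΔCt convention geNorm and NormFinder expect).  The minimum-Ct
sample of each gene is its calibrator, so `max_s Q(g, s) = 1` and Q
decreases monotonically in Ct.  Empirical per-gene bases are used by
the quantification module, not by the stability defaults.

## Stability statistics

**Comparative ΔCt.**  For each ordered pair (j, k) the per-sample
difference `Ct_j − Ct_k` is formed over pairwise-complete samples
(≥3 required, else the pair is dropped with a warning); the score is
the mean of the pairwise SDs.  The SD uses the n−1 denominator — the
originating description does not specify it, and n−1 matches common
spreadsheet practice.  Per-sample loading offsets cancel exactly in
the differences.

**geNorm.**  `M_j` is the mean over partners of the SD of
`log2(Q_j/Q_k)`.  Log base 2 is used throughout; with base-2
quantities each pairwise SD equals the corresponding ΔCt pairwise SD
(the log2 of a ratio of 2^−ΔCt terms is a Ct difference), an
algebraic identity the test suite pins.  Ranking removes the
highest-M gene per step until two remain; the final pair is reported
tied at rank 1 (displayed `A|B`) with the next gene at rank 3,
because the last two genes' M values are by construction identical
(each is the SD of their mutual log ratio).  A tie in the worst M is
broken by dropping the lexicographically last gene, and the tie is
logged.  M values below 1.5 are treated as acceptable by default
(configurable; the stricter 0.5 cutoff used for homogeneous sample
sets is noted but not the default here, since heterogeneous
multi-tissue panels routinely exceed it).  Pairwise variation
`V_n/n+1` is the SD over samples of `log2(NF_n/NF_{n+1})` for
n = 2..G−1, NF being the geometric mean of the top-n quantities.  The
decision rule reports the first n with `V < 0.15`; when no V passes,
the V-minimizing n is reported with an explicit `threshold_met=False`
flag instead of silence.

**NormFinder.**  Log2 quantities are modelled as
`y_igj = α_ig + b_gj + ε_igj` with `ε ~ N(0, σ²_ig)`: a gene-group
expression level, a sample loading effect common to all genes, and
gene-specific noise.  Within each group, two-way centering removes
gene and sample means; because the sample mean mixes every gene's
noise into each residual, the naive residual variance `v_i` is biased
and is corrected as `σ̂²_i = v_i·m/(m−2) − Σv/((m−1)(m−2))` (m genes,
negatives truncated at zero — hence the ≥3-gene requirement).  The
inter-group deviation `d_ig` (gene effect minus its size-weighted
across-group mean) is shrunk toward zero by its estimation variance
`z₀ = σ̂²_ig/n_g` via the factor `γ²/(γ² + z₀)`, where
`γ² = Σd²/((m−1)(G−1)) − mean(z₀)` estimates the dispersion of true
group differences.  The stability value averages
`|d̃_ig| + sqrt(z₀ + Var(d̃_ig))` over groups, combining systematic
group bias with the intra-group dispersion contribution; with a
single group (or no grouping) it reduces to `sqrt(σ̂²_i)`.  No
reference implementation is bundled or wrapped; the test suite
cross-checks against an independent loop-based re-derivation of the
same estimators.  The grouping factor is configurable; the standard
panels use species when organs are pooled and organ within a single
species.

**BestKeeper.**  Works on raw Ct.  The default SD is the mean
absolute deviation from the gene's geometric-mean Ct — the original
tool's convention — with the ordinary sample SD available as
`sd_mode="sample_sd"` because published wording is often ambiguous;
both modes are covered by tests.  CV is SD as a percentage of the
arithmetic mean Ct.  The index is the per-sample geometric mean of
the candidates' Cts and each gene is correlated against it (Pearson r
with a two-sided t-test p).  BestKeeper is intentionally *not*
loading-invariant; a regression test pins this contrast against the
ratio-based methods.

**Consensus.**  Orderings become competition ranks (tied genes share
the smaller rank; the following rank is skipped), and a gene's
comprehensive score is the unweighted geometric mean of its four
ranks.  Equal weighting reproduces every published worked example
checked by the suite, so no hidden weighting is assumed.  Exact score
ties are flagged and ordered by comparing the tied genes' per-method
ranks in method order (ΔCt, BestKeeper, NormFinder, geNorm), then
lexicographically; this deterministic rule also reproduces the
reference dataset's printed orders, which a pure lexicographic
tie-break would not.  Gene identifiers are normalized for case,
hyphens and underscores before cross-method matching.  If one method
fails on a subset, the consensus is computed over the remaining
methods with the failure recorded and warned about — never silently.

## Efficiency and quantification

Standard curves are OLS fits of Ct on log10 relative template amount
(≥3 distinct dilution levels; a non-negative slope is an assay
failure).  Dilutions are encoded as log10 of *relative* amount
(0, −1, −2, …), so absolute concentrations are never needed.
Efficiency is `E[%] = (10^(−1/slope) − 1) × 100`; QC defaults are
90–110% and R² > 0.98, both configurable.

Pfaffl ratios are computed in log space:
`R(s) = E_t^(Ct_t(cal) − Ct_t(s)) / NF(s)` with NF the geometric mean
of the reference genes' efficiency-corrected fold changes.  The
calibrator defaults to the target's minimum-Ct sample (configurable
to a named sample); its own ratio is 1 by definition.  With all bases
2 the formula reduces exactly to 2^−ΔΔCt.  Group summaries report
mean ± standard error over biological replicates, and the
normalizer-comparison utility reports the mean within-group CV of
ratios under each normalizer set plus their ratio.

## Synthetic data

The generator draws
`Ct(g, s) = μ_g + loading_s + δ_{g, level(s)} + ε`, `ε ~ N(0, σ_g)`,
over an organs × species × replicates design (default 3 × 3 × 4 = 36
biological samples, matching the reference study's layout), with
optional technical replicates (extra 0.15-cycle well noise) and a
detection cutoff (40 cycles) above which values go missing.  Normal
noise on the cycle scale is the standard model for qPCR replicate
error; heavier-tailed alternatives and informative dropout are
deliberately out of scope.

The `paper_shape_preset` mirrors the reference study's observable
structure: twelve candidates with baselines spanning 19.53 (EF-1γ,
high expression) to 24.74 (TUB, low), a common organ expression
effect ordered flower (−3) < leaf (0) < rhizome (+4) so flower means
sit near 16.5 cycles, organ-specific loading SDs (0.3/0.5/1.2 cycles,
rhizomes noisiest), per-gene noise SDs spanning 0.2 (SKD1-like) to
2.0 (YLS8-like, which also carries a rhizome-specific shift), and two
regulated targets (PAL up 2 log2 units in flowers and down 1 in
rhizomes beyond the common organ effect; CHS up 3 in flowers).  At
these defaults essentially all draws stay inside the study's observed
13.49–35.12 Ct range.  Ground truth measures each gene's instability
as `sqrt(σ_g² + Var(shift))` with shifts taken *relative to the
per-level median across references*, because components shared by the
whole panel cancel in normalization; target fold changes are recorded
on the same relative basis.

What passing tests on this generator show: the estimators recover
designed noise orderings and fold changes under Gaussian cycle-scale
noise with loading confounding and organ/species structure.  What
they do not show: robustness to non-Gaussian error, informative
dropout near the detection limit, inter-run batch effects, or primer
competition — real datasets can violate all of these.

## Numerical choices and edge cases

Pairwise statistics use pairwise-complete observations with explicit
minimum counts (3 samples per ΔCt pair, 2 per geNorm pair, 3
observations per BestKeeper gene); failures downgrade to missing
entries with warnings rather than aborting a whole panel.  Negative
NormFinder variance estimates truncate at zero.  Zero-variance genes
get undefined (missing) index correlations.  Geometric means are
computed as exp-mean-log throughout.  Competition ranks come from
`rank(method="min")`.  Consensus scores are kept at full precision
and rounded to two decimals only for display.

## Problem sizes

The default test suite and the acceptance script run on 12 genes × 36
samples (the study-shaped design), 50-seed Monte-Carlo batches for
recovery checks, and 5–8-gene random matrices for oracle equivalence;
a full run completes in well under a minute on one CPU.
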