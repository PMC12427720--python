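# refstab

Reference-gene stability analysis for qPCR quantification-cycle (Ct)
data.

Relative expression measured by qRT-PCR is only as reliable as the
internal control it is normalized against, and supposedly stable
housekeeping genes routinely drift with tissue, species and
treatment.  `refstab` implements the standard candidate-validation
toolkit — the comparative ΔCt method, geNorm, NormFinder and
BestKeeper, combined into a RefFinder-style comprehensive ranking —
together with standard-curve amplification-efficiency estimation,
efficiency-corrected (Pfaffl) relative quantification and a synthetic
Ct-data generator with ground-truth stability labels.  It is aimed at
molecular biologists validating reference panels (the shipped
reference dataset is a three-species, three-organ knotweed survey of
twelve candidates) and at methodologists who want the four
statistics, their invariances and their disagreements in one tested,
scriptable package.

## The statistics

With Ct values `Ct(g, s)` per gene and sample, and relative
quantities `Q(g, s) = E_g^(minCt_g − Ct(g, s))` (fold-per-cycle base
`E_g`, 2.0 for ideal doubling, so the minimum-Ct sample is each
gene's calibrator):

* **Comparative ΔCt** — gene j's score is the mean over partners k of
  `SD_s(Ct_j − Ct_k)`; constant pairwise differences mean joint
  stability.
* **geNorm** — `A_jk = SD_s(log2 Q_j/Q_k)`, `M_j = mean_k A_jk`;
  iterated exclusion of the highest-M gene leaves a tied best pair;
  pairwise variation `V_n/n+1 = SD_s(log2 NF_n/NF_{n+1})` of
  normalization factors (geometric means of the top-n quantities)
  decides how many genes a normalizer needs (first `V < 0.15`).
* **NormFinder** — a two-way model of log quantities with
  sample-loading and gene-group effects; per-gene intra-group
  variance (multi-gene bias correction, negatives truncated) and
  shrunken inter-group deviation combine into a stability value `S`;
  lower is more stable.
* **BestKeeper** — descriptives on raw Ct: SD (mean absolute
  deviation from the geometric-mean Ct, or sample SD), CV, and
  Pearson `r` of each gene against the index (per-sample geometric
  mean Ct).  Deliberately *not* invariant to loading offsets.
* **Consensus** — each method's ordering becomes competition ranks
  (ties share the smaller rank, the next is skipped); a gene's
  comprehensive score is the geometric mean of its four ranks.
* **Efficiency / Pfaffl** — `E[%] = (10^(−1/slope) − 1) × 100` from a
  dilution-series OLS fit; target ratios
  `R(s) = E_t^(ΔCt_t) / geomean_r E_r^(ΔCt_r)` reduce to 2^−ΔΔCt at
  `E = 2`.

## Worked example

Rebuilding a comprehensive ranking from per-method rank rows
(`examples/02_published_consensus.py`, using the packaged reference
dataset):

```
gene      ΔCt  BK  NF  geNorm  geomean
SKD1        2   1   3      1    1.57
60SrRNA     1   3   2      3    2.06
ACT         3   4   5      1    2.78
eIF6A       4   6   1      7    3.60
...
TUB        11  12  11     11   11.24
YLS8       12  10  12     12   11.47
```

SKD1 is ranked 2nd by ΔCt, 1st by BestKeeper, 3rd by NormFinder and
shares geNorm's tied first place, so its comprehensive score is
`(2·1·3·1)^(1/4) = 1.57` — the most stable candidate across all
samples; YLS8 and TUB anchor the unstable end and should not be used
as normalizers.  Running the synthetic pipeline end to end
(`examples/01_simulate_and_rank.py`) recovers the generator's true
noise ordering, and `examples/04_pfaffl_quantification.py` shows
within-organ CVs of target ratios inflating from 27% to 72% when
normalization switches from the three most stable to the two least
stable simulated references.

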