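"""Comparative ΔCt stability.

For every gene pair (j, k) the per-sample difference Ct_j − Ct_k is
formed; a stable pair keeps a constant difference across samples, so
the sample standard deviation of the differences measures their joint
instability.  A gene's score is its mean pairwise SD against all other
genes; lower is more stable.  Because any per-sample loading offset
cancels in the difference, the method is invariant to global loading
differences between samples.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .core import CtMatrix
from .results import StabilityResult

__all__ = ["pairwise_delta_sd", "delta_ct_stability"]

#: Minimum jointly observed samples required for a pair's SD.
MIN_PAIR_OBS = 3


def pairwise_delta_sd(ct: CtMatrix, min_obs: int = MIN_PAIR_OBS) -> pd.DataFrame:
    """Gene × gene matrix of SDs of pairwise Ct differences.

    Entry (j, k) is the sample (n−1 denominator) standard deviation of
    Ct_j − Ct_k over samples where both genes are observed; the
    diagonal is 0 and the matrix is symmetric.  Pairs with fewer than
    ``min_obs`` complete samples get ``NaN`` plus a warning.
    """
    genes = ct.genes
    vals = ct.values.to_numpy()
    n = len(genes)
    out = np.zeros((n, n))
    for j, k in itertools.combinations(range(n), 2):
        both = ~np.isnan(vals[j]) & ~np.isnan(vals[k])
        if both.sum() < min_obs:
            warnings.warn(
                f"pair ({genes[j]}, {genes[k]}) has only {int(both.sum())} complete "
                f"samples (<{min_obs}); SD left missing",
                UserWarning,
                stacklevel=2,
            )
            out[j, k] = out[k, j] = np.nan
            continue
        diff = vals[j, both] - vals[k, both]
        out[j, k] = out[k, j] = float(np.std(diff, ddof=1))
    return pd.DataFrame(out, index=genes, columns=genes)


def delta_ct_stability(ct: CtMatrix, subset: str = "all") -> StabilityResult:
    """Rank genes by mean SD of their pairwise Ct differences."""
    if ct.n_genes < 2:
        raise ValueError("comparative ΔCt needs at least 2 genes")
    sd = pairwise_delta_sd(ct)
    arr = sd.to_numpy().astype(float)
    np.fill_diagonal(arr, np.nan)  # exclude self-comparison from the mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = pd.Series(np.nanmean(arr, axis=1), index=sd.index)
    return StabilityResult.from_scores("delta_ct", scores, subset, pairwise_sd=sd)
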