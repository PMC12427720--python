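"""NormFinder model-based stability analysis.

The model treats the log relative quantity of gene i in sample j of
group g as

    y_igj = alpha_ig + b_gj + eps_igj,   eps ~ N(0, sigma2_ig)

where ``b_gj`` is a sample-specific loading effect (shared by all
genes, hence removed by centering each sample over genes),
``alpha_ig`` carries a gene's systematic group-specific expression
and ``sigma2_ig`` its intra-group noise.  A candidate reference gene
is penalized both for inter-group deviation

    d_ig = alpha_ig - mean_g(alpha_ig)

and for intra-group variance.  Because the sample centering mixes all
genes' noise into every residual, the naive per-gene residual variance
is biased; the multi-gene correction

    sigma2_i = v_i * m/(m-2) - sum_i' v_i' / ((m-1)(m-2))

(m = number of genes, negative estimates truncated at 0) removes the
shared component.  The observed d is shrunk toward 0 by its estimation
variance before entering the stability value

    S_i = mean over groups of |d~_ig| + sqrt(sigma2_ig/n_g + Var(d~_ig))

so S combines systematic bias and noise on the log2 scale; lower is
more stable.  With a single group (or no grouping) S reduces to the
square root of the corrected intra-group variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GroupDesign, QuantityMatrix
from .results import StabilityResult, competition_ranks

__all__ = ["NormfinderResult", "normfinder_stability", "normfinder_ungrouped"]


@dataclass
class NormfinderResult:
    """Stability values S with per-group decomposition."""

    stability: pd.Series  # per-gene S, log2 units
    ranks: pd.Series
    grouped: bool
    intergroup: pd.DataFrame = field(default_factory=pd.DataFrame)  # d~, genes x groups
    intragroup_var: pd.DataFrame = field(default_factory=pd.DataFrame)  # genes x groups
    subset: str = "all"

    def to_stability_result(self) -> StabilityResult:
        return StabilityResult(
            "normfinder", self.stability, self.ranks, self.subset,
            {"grouped": self.grouped},
        )


def _corrected_gene_variance(y: np.ndarray) -> np.ndarray:
    """Per-gene residual variance after two-way centering, with the
    multi-gene bias correction (truncated at 0).

    ``y`` is genes × samples on the log2 scale, no missing values
    among the used cells (NaN-aware means are used for robustness).
    """
    m, n = y.shape
    if m < 3:
        raise ValueError("the variance decomposition needs at least 3 genes")
    if n < 2:
        raise ValueError("needs at least 2 samples")
    gene_mean = np.nanmean(y, axis=1, keepdims=True)
    sample_mean = np.nanmean(y, axis=0, keepdims=True)
    grand = np.nanmean(y)
    resid = y - gene_mean - sample_mean + grand
    v = np.nansum(resid**2, axis=1) / (n - 1)
    sigma2 = v * m / (m - 2) - v.sum() / ((m - 1) * (m - 2))
    return np.maximum(sigma2, 0.0)


def normfinder_ungrouped(q: QuantityMatrix, subset: str = "all") -> NormfinderResult:
    """No-group NormFinder variant: S_i = sqrt(corrected variance).

    Sample (loading) and gene (baseline) effects are removed by
    two-way centering; the remaining per-gene residual dispersion is
    the stability value.
    """
    y = q.log2().to_numpy()
    sigma2 = _corrected_gene_variance(y)
    s = pd.Series(np.sqrt(sigma2), index=q.genes)
    return NormfinderResult(
        stability=s,
        ranks=competition_ranks(s),
        grouped=False,
        intragroup_var=pd.DataFrame({"all": sigma2}, index=q.genes),
        subset=subset,
    )


def normfinder_stability(
    q: QuantityMatrix, design: GroupDesign, subset: str = "all"
) -> NormfinderResult:
    """Grouped NormFinder stability values.

    Requires ≥3 genes and every group of size ≥2.  With a single
    group the result equals :func:`normfinder_ungrouped`.
    """
    if len(q.genes) < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    sizes = design.groups.loc[[s for s in q.samples]].value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(f"group(s) of size 1 not allowed: {list(singletons.index)}")
    labels = design.labels()
    if len(labels) == 1:
        res = normfinder_ungrouped(q, subset)
        return NormfinderResult(
            res.stability, res.ranks, True, res.intergroup, res.intragroup_var, subset
        )

    y_all = q.log2()
    genes = q.genes
    m = len(genes)
    g_count = len(labels)

    # per-group corrected intra-group variances and gene effects a_ig
    sigma2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    a = pd.DataFrame(index=genes, columns=labels, dtype=float)
    n_g = {}
    for lab in labels:
        members = [s for s in design.members(lab) if s in y_all.columns]
        block = y_all[members].to_numpy()
        n_g[lab] = block.shape[1]
        sigma2[lab] = _corrected_gene_variance(block)
        # gene effect within group, loading removed by sample centering
        centered = block - np.nanmean(block, axis=0, keepdims=True)
        a[lab] = np.nanmean(centered, axis=1)

    # inter-group deviation: gene effect relative to its size-weighted mean
    weights = np.array([n_g[lab] for lab in labels], dtype=float)
    weights /= weights.sum()
    d = a.sub(a.mul(weights, axis=1).sum(axis=1), axis=0)

    # estimation variance of d and shrinkage of d toward 0
    z0 = sigma2.div(pd.Series(n_g))
    gamma2 = max(
        float((d**2).to_numpy().sum()) / ((m - 1) * (g_count - 1))
        - float(z0.to_numpy().mean()),
        0.0,
    )
    if gamma2 == 0.0:
        d_shrunk = d * 0.0
        var_d = z0 * 0.0
    else:
        shrink = gamma2 / (gamma2 + z0)
        d_shrunk = d * shrink
        var_d = z0 * shrink

    measure = d_shrunk.abs() + np.sqrt(z0 + var_d)
    s = measure.mean(axis=1)
    return NormfinderResult(
        stability=s,
        ranks=competition_ranks(s),
        grouped=True,
        intergroup=d_shrunk,
        intragroup_var=sigma2,
        subset=subset,
    )
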