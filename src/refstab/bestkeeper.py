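"""BestKeeper descriptive stability analysis.

BestKeeper works on raw Ct values, not relative quantities: per gene
it reports the geometric and arithmetic mean Ct, min/max, a dispersion
statistic SD (by default the mean absolute deviation of Ct from the
gene's geometric-mean Ct, the original tool's convention; the sample
standard deviation is offered as an alternative), and the coefficient
of variation CV = SD / mean Ct × 100.  The BestKeeper index is the
per-sample geometric mean of all candidate genes' Ct values; each
gene's Pearson correlation with the index indicates how well it
follows the common trend.  Because Cts are analyzed directly,
BestKeeper — unlike ΔCt, geNorm and NormFinder — is deliberately
sensitive to per-sample loading offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CtMatrix
from .results import StabilityResult, competition_ranks

__all__ = [
    "BestkeeperResult",
    "bestkeeper_stats",
    "bestkeeper_index",
    "index_correlations",
]

MIN_OBS = 3


@dataclass
class BestkeeperResult:
    """Descriptive table plus index correlations and SD-based ranks."""

    table: pd.DataFrame  # per-gene descriptive stats
    index: pd.Series  # per-sample geometric mean Ct
    ranks: pd.Series  # ascending by SD
    sd_mode: str
    subset: str = "all"

    def to_stability_result(self) -> StabilityResult:
        return StabilityResult(
            "bestkeeper", self.table["sd"], self.ranks, self.subset,
            {"sd_mode": self.sd_mode},
        )


def bestkeeper_index(ct: CtMatrix, genes=None) -> pd.Series:
    """Per-sample geometric mean Ct over the selected genes.

    Samples missing any selected gene get a missing index value (with
    a warning); the index is only meaningful over complete samples.
    """
    genes = list(genes) if genes is not None else ct.genes
    block = ct.values.loc[genes]
    incomplete = block.isna().any(axis=0)
    if incomplete.any():
        warnings.warn(
            f"index missing for samples {list(block.columns[incomplete])}",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        logs = np.log(block)
    idx = np.exp(logs.mean(axis=0, skipna=False))
    idx.name = "bestkeeper_index"
    return idx


def index_correlations(ct: CtMatrix, genes=None, index_genes=None) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each gene's Ct against the index.

    The index is built from ``index_genes`` (default: the same genes
    being correlated).  Genes with zero variance over the paired
    observations get missing r/p.  At least 3 paired observations are
    required per gene.
    """
    genes = list(genes) if genes is not None else ct.genes
    idx = bestkeeper_index(ct, index_genes if index_genes is not None else genes)
    rows = []
    for g in genes:
        x = ct.values.loc[g]
        both = x.notna() & idx.notna()
        if both.sum() < MIN_OBS:
            rows.append({"gene": g, "r": np.nan, "p": np.nan})
            continue
        xv, iv = x[both].to_numpy(), idx[both].to_numpy()
        if np.std(xv) == 0 or np.std(iv) == 0:
            rows.append({"gene": g, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(xv, iv)
        rows.append({"gene": g, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")


def bestkeeper_stats(
    ct: CtMatrix, sd_mode: str = "mad_geomean", subset: str = "all"
) -> BestkeeperResult:
    """Per-gene BestKeeper descriptives, index and SD ranking.

    ``sd_mode='mad_geomean'`` (default): SD is the mean absolute
    deviation of Ct from the gene's geometric-mean Ct, the original
    BestKeeper convention.  ``sd_mode='sample_sd'``: ordinary sample
    standard deviation (n−1).  CV = SD / arithmetic mean Ct × 100.
    Genes observed in fewer than 3 samples are excluded with a
    warning.
    """
    if sd_mode not in {"mad_geomean", "sample_sd"}:
        raise ValueError(f"sd_mode must be 'mad_geomean' or 'sample_sd', got {sd_mode!r}")
    usable, dropped = [], []
    for g in ct.genes:
        (usable if ct.values.loc[g].notna().sum() >= MIN_OBS else dropped).append(g)
    if dropped:
        warnings.warn(
            f"genes with <{MIN_OBS} observations excluded: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no gene has enough observations for BestKeeper")

    rows = []
    for g in usable:
        x = ct.values.loc[g].dropna().to_numpy()
        geo = float(np.exp(np.mean(np.log(x))))
        mean = float(np.mean(x))
        if sd_mode == "mad_geomean":
            sd = float(np.mean(np.abs(x - geo)))
        else:
            sd = float(np.std(x, ddof=1))
        rows.append(
            {
                "gene": g,
                "n": len(x),
                "geo_mean_ct": geo,
                "mean_ct": mean,
                "min_ct": float(x.min()),
                "max_ct": float(x.max()),
                "sd": sd,
                "cv_percent": 100.0 * sd / mean,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    corr = index_correlations(ct, usable)
    table = table.join(corr)
    idx = bestkeeper_index(ct, usable)
    ranks = competition_ranks(table["sd"])
    return BestkeeperResult(table, idx, ranks, sd_mode, subset)
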