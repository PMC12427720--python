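"""geNorm expression-stability analysis.

For each gene pair (j, k) the pairwise variation A_jk is the standard
deviation over samples of log2(Q_j / Q_k); a gene's expression
stability M is the mean A against all other candidates (lower = more
stable).  Ranking proceeds by iterated exclusion: the worst (highest
M) gene is dropped and M recomputed until two genes remain, which are
reported as a tied best pair — their mutual log-ratio SD is identical,
so they cannot be separated.

geNorm also decides how many reference genes a normalization factor
(NF, the geometric mean of the top-n genes' quantities) needs: the
pairwise variation V_n/n+1 is the SD over samples of
log2(NF_n / NF_{n+1}); the first n with V below a cutoff
(conventionally 0.15) is deemed sufficient.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QuantityMatrix
from .results import StabilityResult

__all__ = [
    "GenormTrace",
    "genorm_m",
    "genorm_rank",
    "normalization_factor",
    "pairwise_variation",
    "DEFAULT_M_THRESHOLD",
    "DEFAULT_V_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: M values below this are conventionally acceptable for a reference gene.
DEFAULT_M_THRESHOLD = 1.5
#: V_n/n+1 below this means n reference genes suffice.
DEFAULT_V_THRESHOLD = 0.15


def _log2q(q: QuantityMatrix, genes) -> pd.DataFrame:
    sub = q.values.loc[list(genes)]
    if (sub <= 0).any().any():
        bad = sub.columns[(sub <= 0).any(axis=0)].tolist()
        warnings.warn(
            f"non-positive quantities treated as missing in samples {bad}",
            UserWarning,
            stacklevel=3,
        )
        sub = sub.mask(sub <= 0)
    with np.errstate(divide="ignore"):
        return np.log2(sub)


def genorm_m(q: QuantityMatrix, genes=None) -> pd.Series:
    """Per-gene stability M over the given gene subset (default: all).

    M_j = mean over k≠j of SD_samples(log2(Q_j/Q_k)), computed on
    pairwise-complete observations.  With base-2 quantities this SD
    equals the comparative ΔCt pairwise SD (log2 of 2^−ΔCt ratios
    reduces to Ct differences).
    """
    genes = list(genes) if genes is not None else q.genes
    if len(genes) < 2:
        raise ValueError("geNorm M needs at least 2 genes")
    logq = _log2q(q, genes).to_numpy()
    n = len(genes)
    a = np.zeros((n, n))
    for j, k in itertools.combinations(range(n), 2):
        both = ~np.isnan(logq[j]) & ~np.isnan(logq[k])
        if both.sum() < 2:
            warnings.warn(
                f"pair ({genes[j]}, {genes[k]}) has <2 complete samples; "
                "excluded from M",
                UserWarning,
                stacklevel=2,
            )
            a[j, k] = a[k, j] = np.nan
            continue
        ratio = logq[j, both] - logq[k, both]
        a[j, k] = a[k, j] = float(np.std(ratio, ddof=1))
    np.fill_diagonal(a, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pd.Series(np.nanmean(a, axis=1), index=genes)


@dataclass
class GenormTrace:
    """Full record of the iterative geNorm exclusion procedure."""

    steps: list[dict] = field(default_factory=list)  # gene set, M values, excluded
    final_pair: tuple[str, str] = ("", "")
    ordering: list[str] = field(default_factory=list)  # most→least stable
    ranks: pd.Series = field(default_factory=pd.Series)  # tied pair at 1, next 3
    m_at_exclusion: pd.Series = field(default_factory=pd.Series)

    def ranking_display(self) -> list[str]:
        """Ordering with the tied pair shown as ``"A|B"``."""
        a, b = self.final_pair
        return [f"{a}|{b}"] + self.ordering[2:]

    def to_stability_result(self, subset: str = "all") -> StabilityResult:
        scores = self.m_at_exclusion.reindex(self.ordering)
        return StabilityResult(
            "genorm", scores, self.ranks.reindex(self.ordering), subset,
            {"trace": self},
        )


def genorm_rank(q: QuantityMatrix, subset: str = "all") -> GenormTrace:
    """Iterated-exclusion geNorm ranking; needs ≥3 genes.

    At each step the gene with the highest M is removed (ties broken
    by dropping the lexicographically last gene, logged) until two
    remain; those two share rank 1 and the next gene gets rank 3
    (competition ranking), earlier exclusions following in reverse
    order.  Each gene's reported score is its M at the step it was
    excluded; the final pair keep their (equal) two-gene M.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 genes")
    remaining = list(genes)
    steps: list[dict] = []
    excluded: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m(q, remaining)
        worst_val = m.max()
        worst_set = sorted(m.index[m == worst_val])
        if len(worst_set) > 1:
            logger.info("geNorm tie at M=%.6g between %s; dropping %s",
                        worst_val, worst_set, worst_set[-1])
        worst = worst_set[-1]
        steps.append({"genes": list(remaining), "m": m, "excluded": worst})
        m_at_exclusion[worst] = float(m[worst])
        remaining.remove(worst)
        excluded.append(worst)
    m_final = genorm_m(q, remaining)
    steps.append({"genes": list(remaining), "m": m_final, "excluded": None})
    pair = tuple(sorted(remaining))
    for g in pair:
        m_at_exclusion[g] = float(m_final[g])
    ordering = list(pair) + excluded[::-1]
    ranks = pd.Series(
        [1, 1] + list(range(3, len(ordering) + 1)), index=ordering, dtype=int
    )
    return GenormTrace(
        steps=steps,
        final_pair=pair,  # type: ignore[arg-type]
        ordering=ordering,
        ranks=ranks,
        m_at_exclusion=pd.Series(m_at_exclusion).reindex(ordering),
    )


def normalization_factor(q: QuantityMatrix, ranked_genes, n: int) -> pd.Series:
    """Per-sample NF_n: geometric mean of the top-n genes' quantities.

    A sample missing any of the top-n genes gets a missing NF (with a
    warning).  ``n`` may be 1 (single best gene) up to the number of
    ranked genes.
    """
    ranked = list(ranked_genes)
    if not 1 <= n <= len(ranked):
        raise ValueError(f"n must be in [1, {len(ranked)}], got {n}")
    top = ranked[:n]
    logq = _log2q(q, top)
    missing = logq.isna().any(axis=0)
    if missing.any():
        warnings.warn(
            f"NF_{n} missing for samples {list(logq.columns[missing])}",
            UserWarning,
            stacklevel=2,
        )
    nf = np.power(2.0, logq.mean(axis=0, skipna=False))
    nf.name = f"NF_{n}"
    return nf


def pairwise_variation(
    q: QuantityMatrix,
    trace: GenormTrace,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> dict:
    """V_n/n+1 profile and the how-many-genes decision.

    V_n/n+1 = SD over samples of log2(NF_n / NF_{n+1}) for
    n = 2..G−1, NF built from the trace's ranked ordering.  The
    recommended gene count is the first n with V < ``threshold``; when
    no V passes, the n minimizing V is reported with
    ``threshold_met=False``.
    """
    ordering = trace.ordering
    g = len(ordering)
    if g < 3:
        raise ValueError("pairwise variation needs at least 3 ranked genes")
    v = {}
    nf_prev = normalization_factor(q, ordering, 2)
    for n in range(2, g):
        nf_next = normalization_factor(q, ordering, n + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(nf_prev / nf_next)
        v[n] = float(np.nanstd(ratio.to_numpy(), ddof=1))
        nf_prev = nf_next
    passing = [n for n, val in v.items() if val < threshold]
    if passing:
        chosen, met = passing[0], True
    else:
        chosen, met = min(v, key=v.get), False
    return {"v": v, "threshold": threshold, "n_sufficient": chosen, "threshold_met": met}
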