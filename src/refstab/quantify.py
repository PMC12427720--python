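"""Efficiency-corrected relative quantification (Pfaffl method).

The expression ratio of a target gene t in sample s relative to a
calibrator sample, normalized by one or more reference genes r, is

    R(s) = base_t**(Ct_t(cal) - Ct_t(s)) / NF(s)
    NF(s) = geometric mean over r of base_r**(Ct_r(cal) - Ct_r(s))

where each ``base`` is the gene's fold-per-cycle amplification
(1 + E%/100; exactly 2 for ideal doubling, in which case the single-
reference formula reduces to 2^-ΔΔCt).  The calibrator's own ratio is
1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CtMatrix

__all__ = [
    "ExpressionProfile",
    "pfaffl_ratio",
    "compare_normalizers",
    "base_from_percent",
]


def base_from_percent(efficiency_percent: float) -> float:
    """Fold-per-cycle base from percent efficiency (100% → 2.0)."""
    return 1.0 + efficiency_percent / 100.0


@dataclass
class ExpressionProfile:
    """Per-sample relative expression ratios for one target gene."""

    target: str
    ratios: pd.Series  # per-sample, > 0
    normalizers: tuple[str, ...]
    calibrator: str
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def group_summary(self, field_name: str) -> pd.DataFrame:
        """Mean ± standard error of the ratio per annotation group."""
        if field_name not in self.annotations.columns:
            raise KeyError(f"unknown annotation field {field_name!r}")
        df = pd.DataFrame(
            {"ratio": self.ratios, "group": self.annotations[field_name]}
        ).dropna()
        g = df.groupby("group")["ratio"]
        return pd.DataFrame(
            {"mean": g.mean(), "se": g.sem(), "n": g.size()}
        )


def _bases_for(genes: Sequence[str], efficiencies) -> pd.Series:
    if isinstance(efficiencies, (int, float)):
        return pd.Series(float(efficiencies), index=list(genes))
    bases = pd.Series(efficiencies, dtype=float).reindex(list(genes))
    if bases.isna().any():
        raise KeyError(
            f"no efficiency base for genes {list(bases.index[bases.isna()])}"
        )
    return bases


def pfaffl_ratio(
    ct: CtMatrix,
    target: str,
    references: Sequence[str],
    efficiencies: float | Mapping[str, float] = 2.0,
    calibrator: str | None = None,
) -> ExpressionProfile:
    """Pfaffl expression ratio of ``target`` vs a reference-gene set.

    ``efficiencies`` gives fold-per-cycle bases per gene (scalar =
    shared base).  The calibrator defaults to the target's
    minimum-Ct sample; it must have a non-missing Ct for the target
    and every reference gene.
    """
    references = list(references)
    if not references:
        raise ValueError("at least one reference gene is required")
    involved = [target] + references
    unknown = set(involved) - set(ct.genes)
    if unknown:
        raise KeyError(f"genes not in Ct matrix: {sorted(unknown)}")
    bases = _bases_for(involved, efficiencies)
    if calibrator is None:
        calibrator = ct.values.loc[target].idxmin()
    if calibrator not in ct.samples:
        raise KeyError(f"calibrator sample {calibrator!r} not in matrix")
    cal_ct = ct.values.loc[involved, calibrator]
    if cal_ct.isna().any():
        raise ValueError(
            f"calibrator {calibrator!r} has missing Ct for "
            f"{list(cal_ct.index[cal_ct.isna()])}"
        )
    # log2 of base**(Ct_cal - Ct_s), per involved gene
    delta = -ct.values.loc[involved].sub(cal_ct, axis=0)
    log2_terms = delta.mul(np.log2(bases), axis=0)
    log2_target = log2_terms.loc[target]
    log2_nf = log2_terms.loc[references].mean(axis=0)
    ratios = np.power(2.0, log2_target - log2_nf)
    ratios.name = target
    return ExpressionProfile(
        target=target,
        ratios=ratios,
        normalizers=tuple(references),
        calibrator=calibrator,
        annotations=ct.annotations.copy(),
    )


def _group_dispersion(profile: ExpressionProfile, field_name: str) -> float:
    """Mean within-group coefficient of variation of the ratios (%)."""
    df = pd.DataFrame(
        {"ratio": profile.ratios, "group": profile.annotations[field_name]}
    ).dropna()
    cvs = []
    for _, grp in df.groupby("group"):
        if len(grp) < 2 or grp["ratio"].mean() == 0:
            continue
        cvs.append(100.0 * grp["ratio"].std(ddof=1) / grp["ratio"].mean())
    if not cvs:
        raise ValueError("no group with >=2 replicates for dispersion")
    return float(np.mean(cvs))


def compare_normalizers(
    ct: CtMatrix,
    targets: Sequence[str],
    stable: Sequence[str],
    unstable: Sequence[str],
    *,
    group_field: str = "organ",
    efficiencies: float | Mapping[str, float] = 2.0,
    calibrator: str | None = None,
) -> dict:
    """Quantify each target under stable vs unstable normalizer sets.

    Returns per-target profiles under both sets plus a dispersion
    summary: the mean within-group CV of ratios under each set and
    their ratio (unstable / stable).  A ratio > 1 means the unstable
    normalizers inflate apparent biological variability.
    """
    stable, unstable = list(stable), list(unstable)
    targets = list(targets)
    if not stable or not unstable:
        raise ValueError("both normalizer sets must be non-empty")
    overlap = (set(stable) | set(unstable)) & set(targets)
    if overlap:
        raise ValueError(f"normalizer sets overlap targets: {sorted(overlap)}")
    out: dict = {"targets": {}, "dispersion": {}}
    disp_s, disp_u = [], []
    for t in targets:
        p_s = pfaffl_ratio(ct, t, stable, efficiencies, calibrator)
        p_u = pfaffl_ratio(ct, t, unstable, efficiencies, calibrator)
        d_s = _group_dispersion(p_s, group_field)
        d_u = _group_dispersion(p_u, group_field)
        disp_s.append(d_s)
        disp_u.append(d_u)
        out["targets"][t] = {
            "stable": p_s,
            "unstable": p_u,
            "cv_stable": d_s,
            "cv_unstable": d_u,
        }
    out["dispersion"] = {
        "cv_stable": float(np.mean(disp_s)),
        "cv_unstable": float(np.mean(disp_u)),
        "ratio_unstable_over_stable": float(np.mean(disp_u) / np.mean(disp_s)),
    }
    return out
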