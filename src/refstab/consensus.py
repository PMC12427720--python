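"""Comprehensive (RefFinder-style) consensus ranking.

Each of the four stability methods produces an ordering of the
candidate genes; converting orderings to competition ranks (a tied
pair shares the smaller rank and the next rank is skipped) and taking
the geometric mean of a gene's four ranks gives its comprehensive
stability score.  The final order sorts ascending by score; exact
score ties are flagged and broken by comparing the genes' per-method
ranks in method order (ΔCt, BestKeeper, NormFinder, geNorm), then
lexicographically.  All four methods are weighted equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bestkeeper import bestkeeper_stats
from .core import CtMatrix, GroupDesign, to_quantities
from .delta_ct import delta_ct_stability
from .genorm import genorm_rank
from .normfinder import normfinder_stability, normfinder_ungrouped
from .results import StabilityResult

__all__ = [
    "METHOD_ORDER",
    "ConsensusRanking",
    "to_competition_ranks",
    "reffinder_geomean",
    "run_all_methods",
    "standard_panels",
    "normalize_gene_id",
]

METHOD_ORDER = ("delta_ct", "bestkeeper", "normfinder", "genorm")


def normalize_gene_id(name: str) -> str:
    """Case- and hyphen-insensitive canonical form for set matching."""
    return name.strip().replace("-", "").replace("_", "").upper()


def to_competition_ranks(ordering: Sequence[str]) -> pd.Series:
    """Ranks from an ordering that may contain one tied pair ``"A|B"``.

    ``["A|B", "C", "D"]`` → A=1, B=1, C=3, D=4.  Every gene must
    appear exactly once (a tied pair counts as two genes).
    """
    ranks: dict[str, int] = {}
    pos = 1
    for item in ordering:
        members = [m.strip() for m in str(item).split("|")] if "|" in str(item) else [str(item).strip()]
        for m in members:
            if not m:
                raise ValueError(f"empty gene name in ordering item {item!r}")
            if m in ranks:
                raise ValueError(f"gene {m!r} appears more than once in the ordering")
            ranks[m] = pos
        pos += len(members)
    return pd.Series(ranks, dtype=int)


@dataclass
class ConsensusRanking:
    """Geometric-mean rank aggregation over the stability methods."""

    method_ranks: pd.DataFrame  # genes x methods (columns in METHOD_ORDER subset)
    scores: pd.Series  # geometric mean of ranks, >= 1
    ordering: list[str]  # most -> least stable
    final_ranks: pd.Series  # competition ranks on the score
    tied: list[tuple[str, ...]] = field(default_factory=list)
    subset: str = "all"
    methods_used: tuple[str, ...] = METHOD_ORDER

    def to_frame(self) -> pd.DataFrame:
        out = self.method_ranks.copy()
        out["geomean"] = self.scores
        out["geomean_2dp"] = self.scores.round(2)
        out["rank"] = self.final_ranks
        return out.loc[self.ordering]


def reffinder_geomean(
    ranks: Mapping[str, pd.Series], subset: str = "all"
) -> ConsensusRanking:
    """Aggregate per-method competition ranks by geometric mean.

    ``ranks`` maps method name → per-gene rank Series; all methods
    must cover the same gene set (after case/hyphen normalization).
    Scores are reported at full precision; display rounding to two
    decimals is left to the caller.
    """
    if not ranks:
        raise ValueError("no method rankings supplied")
    methods = [m for m in METHOD_ORDER if m in ranks] + [
        m for m in ranks if m not in METHOD_ORDER
    ]
    norm_maps = {}
    key_sets = []
    for m in methods:
        s = ranks[m]
        keyed = {normalize_gene_id(g): g for g in s.index}
        norm_maps[m] = keyed
        key_sets.append(set(keyed))
    common = key_sets[0]
    for ks in key_sets[1:]:
        if ks != common:
            diff = common.symmetric_difference(ks)
            raise ValueError(f"method gene sets differ: {sorted(diff)}")

    canonical = {k: norm_maps[methods[0]][k] for k in common}
    table = pd.DataFrame(
        {
            m: {canonical[k]: int(ranks[m][norm_maps[m][k]]) for k in common}
            for m in methods
        }
    )
    scores = pd.Series(
        np.exp(np.log(table.to_numpy(dtype=float)).mean(axis=1)), index=table.index
    )

    def sort_key(gene: str):
        return (scores[gene], *[table.at[gene, m] for m in methods], gene)

    ordering = sorted(table.index, key=sort_key)
    tied = [
        tuple(grp.index)
        for _, grp in scores.groupby(scores)
        if len(grp) > 1
    ]
    for group in tied:
        warnings.warn(
            f"consensus score tie among {group}; order decided by per-method ranks",
            UserWarning,
            stacklevel=2,
        )
    final_ranks = scores.rank(method="min").astype(int)
    return ConsensusRanking(
        method_ranks=table[methods],
        scores=scores,
        ordering=ordering,
        final_ranks=final_ranks,
        tied=tied,
        subset=subset,
        methods_used=tuple(methods),
    )


def run_all_methods(
    ct: CtMatrix,
    design: GroupDesign | None = None,
    subset: str = "all",
    *,
    sd_mode: str = "mad_geomean",
    efficiencies: float = 2.0,
) -> dict:
    """Run ΔCt, geNorm, NormFinder and BestKeeper plus the consensus.

    ``design`` supplies NormFinder's grouping; without one the
    ungrouped variant is used.  A method that fails on the data is
    omitted from the consensus with an explicit warning and listed
    under ``"failed"`` in the returned dict (never silently).
    """
    q = to_quantities(ct, efficiencies)
    results: dict[str, StabilityResult] = {}
    failed: dict[str, str] = {}

    def attempt(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            failed[name] = str(exc)
            warnings.warn(
                f"method {name!r} failed on subset {subset!r}: {exc}; "
                "consensus computed over the remaining methods",
                UserWarning,
                stacklevel=3,
            )

    attempt("delta_ct", lambda: delta_ct_stability(ct, subset))
    attempt("genorm", lambda: genorm_rank(q, subset).to_stability_result(subset))
    if design is not None:
        attempt("normfinder", lambda: normfinder_stability(q, design, subset).to_stability_result())
    else:
        attempt("normfinder", lambda: normfinder_ungrouped(q, subset).to_stability_result())
    attempt("bestkeeper", lambda: bestkeeper_stats(ct, sd_mode, subset).to_stability_result())

    if not results:
        raise RuntimeError(f"all stability methods failed on subset {subset!r}")
    consensus = reffinder_geomean(
        {name: res.ranks for name, res in results.items()}, subset
    )
    return {"methods": results, "consensus": consensus, "failed": failed}


def standard_panels(
    ct: CtMatrix,
    organ_field: str = "organ",
    species_field: str = "species",
    **kwargs,
) -> dict[str, dict]:
    """The seven standard analysis panels: all samples, each organ,
    each species.

    NormFinder grouping follows the panel: species when organs are
    pooled (all-samples and per-organ panels), organ within a single
    species.
    """
    panels: dict[str, dict] = {}
    design_all = GroupDesign.from_annotation(ct, species_field)
    panels["all"] = run_all_methods(ct, design_all, "all", **kwargs)
    for organ in sorted(ct.annotations[organ_field].unique()):
        sub = ct.select(**{organ_field: organ})
        design = GroupDesign.from_annotation(sub, species_field)
        panels[f"{organ_field}:{organ}"] = run_all_methods(sub, design, organ, **kwargs)
    for species in sorted(ct.annotations[species_field].unique()):
        sub = ct.select(**{species_field: species})
        design = GroupDesign.from_annotation(sub, organ_field)
        panels[f"{species_field}:{species}"] = run_all_methods(sub, design, species, **kwargs)
    return panels
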