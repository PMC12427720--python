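"""Shared result container for the four stability methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["StabilityResult", "competition_ranks"]


def competition_ranks(scores: pd.Series, ascending: bool = True) -> pd.Series:
    """Competition ("1224") ranks: ties share the smaller rank and the
    next rank is skipped.  Lower score = better when ``ascending``."""
    r = scores.rank(method="min", ascending=ascending)
    return r.astype(int)


@dataclass
class StabilityResult:
    """Per-gene stability scores and ranks from one method.

    ``method`` is one of ``delta_ct``, ``genorm``, ``normfinder``,
    ``bestkeeper``; ``subset`` labels the analysis panel (e.g. "all
    samples", "leaves").  Lower scores always mean more stable; ranks
    are competition ranks over the scored genes.
    """

    method: str
    scores: pd.Series  # index gene, method-specific units
    ranks: pd.Series  # competition ranks, int
    subset: str = "all"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls, method: str, scores: pd.Series, subset: str = "all", **extras
    ) -> "StabilityResult":
        scores = scores.astype(float)
        return cls(method, scores, competition_ranks(scores), subset, extras)

    def ordering(self) -> list[str]:
        """Genes from most to least stable (ties by score then name)."""
        return list(
            self.scores.to_frame("s")
            .assign(name=lambda d: d.index)
            .sort_values(["s", "name"])
            .index
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.scores.index, "score": self.scores.values, "rank": self.ranks.values}
        ).sort_values("rank", kind="stable").reset_index(drop=True)
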