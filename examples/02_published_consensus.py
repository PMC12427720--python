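"""Rebuild the published comprehensive ranking from its rank rows.

The package ships the per-method stability orderings for seven
analysis panels of a three-species knotweed survey.  Converting each
ordering to competition ranks (the tied geNorm pair shares rank 1)
and taking the geometric mean per gene reproduces the published
comprehensive scores and order.
"""

from refstab.consensus import METHOD_ORDER, reffinder_geomean, to_competition_ranks
from refstab.datasets import load_published_rankings

panels = load_published_rankings()
rows = panels["all"]
ranks = {m: to_competition_ranks(rows[m]) for m in METHOD_ORDER}
cons = reffinder_geomean(ranks, subset="all samples")

print("gene      ΔCt  BK  NF  geNorm  geomean")
for g in cons.ordering:
    r = cons.method_ranks.loc[g]
    print(f"{g:9s} {r['delta_ct']:3d} {r['bestkeeper']:3d} {r['normfinder']:3d} "
          f"{r['genorm']:6d}  {cons.scores[g]:6.2f}")
# SKD1 scores (2*1*3*1)^(1/4) = 1.57: most stable across all samples;
# YLS8 and TUB sit at the bottom, matching the published order.
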