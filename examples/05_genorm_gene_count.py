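"""How many reference genes does a normalization factor need?

geNorm's pairwise variation V_n/n+1 is the SD of log2(NF_n / NF_n+1)
over samples; the first n with V below 0.15 is deemed sufficient.
"""

import warnings

from refstab import paper_shape_preset, simulate_ct, to_quantities
from refstab.genorm import genorm_rank, pairwise_variation

warnings.simplefilter("ignore", UserWarning)

ct, _ = simulate_ct(paper_shape_preset(seed=11))
refs = ct.select(genes=[g for g in ct.genes if g not in ("PAL", "CHS")])
q = to_quantities(refs)

trace = genorm_rank(q)
print("geNorm ranking:", " > ".join(trace.ranking_display()))
print("M at exclusion:", {g: round(m, 3) for g, m in trace.m_at_exclusion.items()})

v = pairwise_variation(q, trace, threshold=0.15)
for n, val in v["v"].items():
    marker = " <- first below 0.15" if v["threshold_met"] and n == v["n_sufficient"] else ""
    print(f"V{n}/{n + 1} = {val:.4f}{marker}")
print(f"recommended number of reference genes: {v['n_sufficient']}"
      + ("" if v["threshold_met"] else " (threshold not met; minimum-V fallback)"))
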