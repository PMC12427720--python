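"""Packaged reference datasets.

Two small tables from the published multi-species knotweed
reference-gene study ship with the package:

* the per-method stability rank orders for all seven analysis panels
  (all samples, three organs, three species), including each geNorm
  tied best pair, plus the published comprehensive orders — the input
  for the desk-reproducible consensus computation;
* the primer amplification efficiencies and calibration R² values
  (per-gene, percent), usable as empirical bases for
  efficiency-corrected quantification and as QC anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_rankings", "load_primer_efficiencies", "PANELS"]

#: Panel labels in the published order.
PANELS = (
    "all",
    "leaves",
    "rhizomes",
    "flowers",
    "R. japonica",
    "R. x bohemica",
    "R. sachalinensis",
)


def _data_path(name: str):
    return resources.files("refstab").joinpath("data", name)


def load_published_rankings() -> dict[str, dict[str, list[str]]]:
    """Per-panel, per-method gene orderings (most → least stable).

    Returns ``{panel: {method: ordering}}`` where ``ordering`` is a
    list of gene names; a geNorm tied pair appears as one ``"A|B"``
    item.  Methods are ``delta_ct``, ``bestkeeper``, ``normfinder``,
    ``genorm`` and the published ``comprehensive`` order.
    """
    with _data_path("published_rankings.csv").open(encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    out: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["panel"], {})[row["method"]] = row["ordering"].split(";")
    return out


def load_primer_efficiencies() -> pd.DataFrame:
    """Published per-gene amplification efficiency [%] and R²."""
    with _data_path("primer_efficiencies.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh).set_index("gene")
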