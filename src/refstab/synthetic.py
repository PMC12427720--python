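"""Synthetic Ct-data generator with ground-truth stability labels.

The generator emulates a multi-organ × multi-species qPCR survey of
candidate reference genes.  Each Ct value is drawn as

    Ct(g, s) = mu_g + loading_s + delta_{g, level(s)} + eps,
    eps ~ Normal(0, sigma_g)

where ``mu_g`` is the gene's baseline quantification cycle,
``loading_s`` a per-sample offset shared by all genes (template
amount / RNA quality; drawn per sample with an organ-specific SD so
that e.g. rhizome-like tissues are noisier), ``delta`` a gene- and
group-specific expression shift (the systematic component that makes
a gene a *bad* reference), and ``sigma_g`` the gene's reaction noise.
Cts above the detection cutoff become missing.

Because loading offsets are shared across genes they cancel in
ratio-based statistics (ΔCt, geNorm, NormFinder) but not in
BestKeeper's raw-Ct descriptives — a discriminating regression
surface for the test suite.

Ground truth orders genes by their true instability
``sqrt(sigma_g**2 + Var(shift across samples))`` and records each
target gene's true log2 fold-changes per group (on the expression
scale, i.e. −delta when the base is 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CtMatrix

__all__ = ["GeneSpec", "SimulationConfig", "GroundTruth", "simulate_ct", "paper_shape_preset"]


@dataclass
class GeneSpec:
    """One simulated gene: baseline Ct, noise SD, group shifts.

    ``shifts`` maps an annotation level (an organ or species name) to
    a Ct shift in cycles; shifts for a sample add over the levels it
    carries.  ``is_target`` marks genes simulated as regulated targets
    rather than reference candidates.
    """

    name: str
    baseline: float
    noise_sd: float
    shifts: dict[str, float] = field(default_factory=dict)
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise SD must be >= 0, got {self.noise_sd}")


@dataclass
class SimulationConfig:
    """Design and noise model for one simulated experiment."""

    genes: list[GeneSpec]
    organs: tuple[str, ...] = ("leaf", "rhizome", "flower")
    species: tuple[str, ...] = ("RJ", "RB", "RS")
    replicates: int = 4
    loading_sd: float | Mapping[str, float] = 0.5  # scalar or per-organ, cycles
    technical_replicates: int = 1
    technical_sd: float = 0.15
    detection_cutoff: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if not self.organs or not self.species:
            raise ValueError("degenerate design: no samples")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in config")

    def sample_shift(self, gene: GeneSpec, organ: str, species: str) -> float:
        return gene.shifts.get(organ, 0.0) + gene.shifts.get(species, 0.0)


@dataclass
class GroundTruth:
    """True stability labels and target fold-changes for a simulation."""

    instability: pd.Series  # per reference gene, cycles; lower = more stable
    ordering: list[str]  # reference genes, most -> least stable
    target_log2fc: pd.DataFrame  # targets x group levels, log2 expression units

    def to_json_dict(self) -> dict:
        return {
            "instability": self.instability.round(6).to_dict(),
            "ordering": self.ordering,
            "target_log2fc": {
                t: self.target_log2fc.loc[t].round(6).to_dict()
                for t in self.target_log2fc.index
            },
        }


def simulate_ct(config: SimulationConfig) -> tuple[CtMatrix, GroundTruth]:
    """Draw one Ct matrix under the configured noise model.

    Sample identifiers are ``{species}{replicate}_{organ}`` (with a
    ``_t{k}`` suffix when technical replicates are simulated);
    annotations carry organ, species and replicate (plus ``tech``).
    Fixed seed → bit-reproducible output.
    """
    rng = np.random.default_rng(config.seed)
    units = [
        (sp, rep, org)
        for sp in config.species
        for rep in range(1, config.replicates + 1)
        for org in config.organs
    ]
    tech = config.technical_replicates
    sample_ids, ann_rows = [], []
    for sp, rep, org in units:
        base_id = f"{sp}{rep}_{org}"
        for t in range(1, tech + 1):
            sid = base_id if tech == 1 else f"{base_id}_t{t}"
            sample_ids.append(sid)
            row = {"organ": org, "species": sp, "replicate": rep}
            if tech > 1:
                row["tech"] = t
            ann_rows.append(row)
    annotations = pd.DataFrame(ann_rows, index=sample_ids)

    loading = {}
    for sp, rep, org in units:
        sd = (
            config.loading_sd.get(org, 0.0)
            if isinstance(config.loading_sd, Mapping)
            else config.loading_sd
        )
        loading[f"{sp}{rep}_{org}"] = rng.normal(0.0, sd) if sd > 0 else 0.0

    values = pd.DataFrame(index=[g.name for g in config.genes], columns=sample_ids, dtype=float)
    for g in config.genes:
        for sp, rep, org in units:
            base_id = f"{sp}{rep}_{org}"
            bio = (
                g.baseline
                + loading[base_id]
                + config.sample_shift(g, org, sp)
                + (rng.normal(0.0, g.noise_sd) if g.noise_sd > 0 else 0.0)
            )
            for t in range(1, tech + 1):
                sid = base_id if tech == 1 else f"{base_id}_t{t}"
                ct = bio + (rng.normal(0.0, config.technical_sd) if tech > 1 else 0.0)
                values.at[g.name, sid] = np.nan if ct > config.detection_cutoff else ct

    truth = _ground_truth(config)
    return CtMatrix(values, annotations), truth


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    """Shifts shared by all reference candidates (e.g. a common organ
    expression effect) cancel in normalization, so both the true
    instability and the true target fold-changes are measured on
    shifts *relative to the per-level median across references*."""
    units = [
        (sp, org)
        for sp in config.species
        for org in config.organs
        for _ in range(config.replicates)
    ]
    refs = [g for g in config.genes if not g.is_target]
    levels = list(config.organs) + list(config.species)
    common = {
        lvl: float(np.median([g.shifts.get(lvl, 0.0) for g in refs])) for lvl in levels
    }

    def rel_shift(g: GeneSpec, org: str, sp: str) -> float:
        return (g.shifts.get(org, 0.0) - common[org]) + (
            g.shifts.get(sp, 0.0) - common[sp]
        )

    inst = {}
    for g in refs:
        shifts = np.array([rel_shift(g, org, sp) for sp, org in units])
        inst[g.name] = float(np.sqrt(g.noise_sd**2 + shifts.var()))
    instability = pd.Series(inst)
    ordering = list(instability.sort_values(kind="stable").index)

    targets = [g for g in config.genes if g.is_target]
    fc = (
        pd.DataFrame(
            {
                lvl: {
                    g.name: -(g.shifts.get(lvl, 0.0) - common[lvl]) for g in targets
                }
                for lvl in levels
            }
        )
        if targets
        else pd.DataFrame(columns=levels)
    )
    return GroundTruth(instability, ordering, fc)


def paper_shape_preset(seed: int = 0, technical_replicates: int = 1) -> SimulationConfig:
    """A 12-candidate + 2-target preset shaped like the knotweed study.

    Twelve reference candidates named after the study's genes with
    baselines spanning ~19.5 (EF-1γ, highest expression) to ~24.7
    (TUB, lowest), organ effects ordered flower < leaf < rhizome,
    organ-specific loading noise (rhizomes the noisiest), gene noise
    SDs that make SKD1/60SrRNA/ACT-like genes stable and
    TUB/YLS8/TUA-like genes unstable, and two regulated targets
    (PAL, CHS) with known organ fold-changes.
    """
    # organ expression shifts common to all genes (transcriptional activity)
    organ_fx = {"flower": -3.0, "leaf": 0.0, "rhizome": 4.0}

    def ref(name, baseline, sd, shifts=None):
        sh = dict(organ_fx)
        for k, v in (shifts or {}).items():
            sh[k] = sh.get(k, 0.0) + v
        return GeneSpec(name, baseline, sd, sh)

    genes = [
        ref("SKD1", 21.0, 0.20),
        ref("60SrRNA", 20.5, 0.30),
        ref("ACT", 21.5, 0.35),
        ref("eIF6A", 22.0, 0.40),
        ref("EF-1γ", 19.53, 0.45),
        ref("NDUFA13", 22.5, 0.50),
        ref("GAPDH", 21.8, 0.60),
        ref("UBC", 22.2, 0.70),
        ref("UBQ", 21.2, 0.80),
        ref("TUA", 23.5, 1.10, {"RS": 1.0}),
        ref("TUB", 24.74, 1.40),
        ref("YLS8", 23.0, 2.00, {"rhizome": 2.0}),
    ]
    targets = [
        GeneSpec(
            "PAL", 24.0, 0.40,
            {**organ_fx, "flower": organ_fx["flower"] - 2.0, "rhizome": organ_fx["rhizome"] + 1.0},
            is_target=True,
        ),
        GeneSpec(
            "CHS", 25.0, 0.40,
            {**organ_fx, "flower": organ_fx["flower"] - 3.0},
            is_target=True,
        ),
    ]
    return SimulationConfig(
        genes=genes + targets,
        organs=("leaf", "rhizome", "flower"),
        species=("RJ", "RB", "RS"),
        replicates=4,
        loading_sd={"flower": 0.3, "leaf": 0.5, "rhizome": 1.2},
        technical_replicates=technical_replicates,
        detection_cutoff=40.0,
        seed=seed,
    )
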