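"""Core data model and I/O for quantification-cycle (Ct) tables.

A :class:`CtMatrix` holds one Ct value (possibly missing) per
(gene, sample) pair plus per-sample annotations (organ, species,
replicate ...).  All downstream stability methods consume either the
Ct matrix directly (ΔCt, BestKeeper) or the relative-quantity
transform ``Q = base**(minCt - Ct)`` (geNorm, NormFinder), where the
minimum-Ct sample of each gene acts as that gene's calibrator so that
``max Q == 1`` per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "GroupDesign",
    "QuantityMatrix",
    "CtValidationError",
    "ReplicateSpreadWarning",
    "read_ct_table",
    "write_ct_table",
    "aggregate_technical_replicates",
    "to_quantities",
    "filter_high_missing_genes",
]

#: Plausible Ct window (cycles).  qPCR instruments rarely report
#: meaningful quantification cycles outside roughly 5–45.
DEFAULT_CT_WINDOW = (5.0, 45.0)

#: Cell contents treated as missing when reading tables.
NA_STRINGS = ("", "NA", "N/A", "NaN", "nan", "Undetermined", "undetermined", "Undet.")


class CtValidationError(ValueError):
    """Raised when a Ct table violates a structural invariant."""


class ReplicateSpreadWarning(UserWarning):
    """Technical replicates of one biological sample disagree by more
    than the QC threshold (default 0.5 cycles)."""


@dataclass
class CtMatrix:
    """Genes × samples matrix of Ct values with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene, columns are samples; ``NaN`` marks a
        missing (undetermined) reaction.
    annotations
        DataFrame indexed by sample; typical columns are ``organ``,
        ``species`` and ``replicate``.  May be empty.
    ct_window
        Inclusive plausibility window for non-missing Ct values.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    ct_window: tuple[float, float] = DEFAULT_CT_WINDOW

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise CtValidationError(f"duplicate gene identifiers: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise CtValidationError(f"duplicate sample identifiers: {dupes}")
        arr = self.values.to_numpy()
        finite = np.isfinite(arr)
        if np.any(~finite & ~np.isnan(arr)):
            raise CtValidationError("non-finite, non-missing Ct value present")
        lo, hi = self.ct_window
        bad = finite & ((arr < lo) | (arr > hi))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CtValidationError(
                f"Ct {arr[g, s]:.2f} for gene {self.values.index[g]!r}, sample "
                f"{self.values.columns[s]!r} outside plausible window [{lo}, {hi}]"
            )
        if self.annotations.empty:
            self.annotations = pd.DataFrame(index=self.values.columns.copy())
        else:
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise CtValidationError(
                    f"samples without annotation rows: {sorted(missing)}"
                )
            self.annotations = self.annotations.loc[self.values.columns]

    # -- basic accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.annotations.copy(), self.ct_window)

    # -- subsetting ------------------------------------------------------

    def select(self, genes: Sequence[str] | None = None, **factors: object) -> "CtMatrix":
        """Subset by gene list and/or annotation factor levels.

        ``ct.select(organ="leaf")`` keeps the samples whose ``organ``
        annotation equals ``"leaf"``; a list/tuple value keeps any of
        the listed levels.  This is the single subset selector used for
        every analysis panel (all samples, per organ, per species).
        """
        vals = self.values
        if genes is not None:
            unknown = set(genes) - set(self.genes)
            if unknown:
                raise KeyError(f"unknown genes: {sorted(unknown)}")
            vals = vals.loc[list(genes)]
        keep = pd.Series(True, index=self.values.columns)
        for factor, level in factors.items():
            if factor not in self.annotations.columns:
                raise KeyError(f"unknown annotation field {factor!r}")
            col = self.annotations[factor]
            if isinstance(level, (list, tuple, set, frozenset)):
                keep &= col.isin(list(level))
            else:
                keep &= col == level
        samples = self.values.columns[keep.to_numpy()]
        if len(samples) == 0:
            raise ValueError(f"subset selection {factors!r} matched no samples")
        return CtMatrix(
            vals[samples].copy(), self.annotations.loc[samples].copy(), self.ct_window
        )


@dataclass
class GroupDesign:
    """Assignment of every sample to exactly one group.

    Used by NormFinder, whose model separates intra-group (noise) from
    inter-group (systematic) expression variation.
    """

    groups: pd.Series  # index: sample, value: group label

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if self.groups.isna().any():
            bad = self.groups.index[self.groups.isna()].tolist()
            raise CtValidationError(f"samples without a group: {bad}")

    @classmethod
    def from_annotation(cls, ct: CtMatrix, factor: str | Sequence[str]) -> "GroupDesign":
        """Build a design from one annotation factor or a factor crossing."""
        factors = [factor] if isinstance(factor, str) else list(factor)
        for f in factors:
            if f not in ct.annotations.columns:
                raise KeyError(f"unknown annotation field {f!r}")
        labels = ct.annotations[factors].astype(str).agg("/".join, axis=1)
        return cls(labels)

    def labels(self) -> list[str]:
        return sorted(self.groups.unique())

    def members(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    def validate_for(self, ct: CtMatrix, min_size: int = 2) -> None:
        missing = set(ct.samples) - set(self.groups.index)
        if missing:
            raise CtValidationError(f"samples without a group: {sorted(missing)}")
        sizes = self.groups.loc[list(ct.samples)].value_counts()
        small = sizes[sizes < min_size]
        if len(small):
            raise CtValidationError(
                f"group(s) below minimum size {min_size}: {dict(small)}"
            )


@dataclass
class QuantityMatrix:
    """Relative quantities ``Q = base**(minCt - Ct)`` per gene.

    The minimum-Ct sample of each gene is the within-gene calibrator,
    so ``max Q == 1`` along each gene row and Q decreases with Ct.
    """

    values: pd.DataFrame  # genes x samples, Q > 0 or NaN
    efficiencies: pd.Series  # per-gene fold-per-cycle base
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> pd.DataFrame:
        """Log2-transformed quantities (NaN preserved)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.values)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CT_HEADER_ALIASES = {"ct", "cq", "ct_value", "cq_value"}


def _read_sample_sheet(path, sep: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    sheet = sheet.set_index(sheet.columns[0])
    return sheet


def read_ct_table(
    path,
    layout: str = "long",
    *,
    sep: str = ",",
    decimal: str = ".",
    genes_in_rows: bool = True,
    sample_sheet=None,
    ct_window: tuple[float, float] = DEFAULT_CT_WINDOW,
) -> CtMatrix:
    """Read a delimited Ct table in long or wide layout.

    Long layout: columns ``gene, sample, ct`` (header ``cq`` also
    accepted) plus optional annotation columns (``organ``, ``species``,
    ``replicate`` ...).  Wide layout: first column gene identifiers
    (or sample identifiers with ``genes_in_rows=False``), remaining
    columns the other axis.  Blank, ``NA`` and ``Undetermined`` cells
    become missing.  A separate sample-sheet CSV (sample, organ,
    species, replicate) may supply annotations for either layout.
    """
    if layout not in {"long", "wide"}:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    if layout == "long":
        df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
        df.columns = [c.strip() for c in df.columns]
        lower = {c.lower(): c for c in df.columns}
        ct_col = next((lower[a] for a in _CT_HEADER_ALIASES if a in lower), None)
        if ct_col is None or "gene" not in lower or "sample" not in lower:
            raise CtValidationError(
                "long layout requires columns gene, sample and ct/cq; got "
                f"{list(df.columns)}"
            )
        gene_col, sample_col = lower["gene"], lower["sample"]
        dup = df.duplicated(subset=[gene_col, sample_col])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise CtValidationError(
                f"duplicate cell for gene {row[gene_col]!r}, sample {row[sample_col]!r}"
            )
        ct_vals = _parse_ct_column(df[ct_col], decimal)
        genes = list(dict.fromkeys(df[gene_col]))
        samples = list(dict.fromkeys(df[sample_col]))
        values = pd.DataFrame(np.nan, index=genes, columns=samples)
        for g, s, v in zip(df[gene_col], df[sample_col], ct_vals):
            values.loc[g, s] = v
        ann_cols = [
            c for c in df.columns if c not in {gene_col, sample_col, ct_col}
        ]
        annotations = pd.DataFrame(index=pd.Index(samples))
        if ann_cols:
            ann = df[[sample_col] + ann_cols].drop_duplicates()
            if ann[sample_col].duplicated().any():
                bad = ann.loc[ann[sample_col].duplicated(), sample_col].iloc[0]
                raise CtValidationError(
                    f"conflicting annotations for sample {bad!r}"
                )
            annotations = ann.set_index(sample_col).loc[samples]
    else:
        df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
        df = df.set_index(df.columns[0])
        if df.index.has_duplicates:
            bad = df.index[df.index.duplicated()][0]
            raise CtValidationError(f"duplicate row identifier {bad!r}")
        parsed = df.apply(lambda col: _parse_ct_column(col, decimal))
        parsed.index = df.index
        values = parsed if genes_in_rows else parsed.T
        values.index.name = None
        values.columns.name = None
        annotations = pd.DataFrame(index=values.columns)

    if sample_sheet is not None:
        sheet = _read_sample_sheet(sample_sheet, sep)
        annotations = annotations.join(sheet, how="left") if not annotations.empty else sheet
        annotations = annotations.loc[values.columns]

    return CtMatrix(values, annotations, ct_window)


def _parse_ct_column(col: pd.Series, decimal: str) -> pd.Series:
    out = []
    for i, raw in enumerate(col):
        s = str(raw).strip()
        if s in NA_STRINGS:
            out.append(np.nan)
            continue
        if decimal != ".":
            s = s.replace(decimal, ".")
        try:
            out.append(float(s))
        except ValueError:
            raise CtValidationError(
                f"non-numeric Ct value {raw!r} at data line {i + 1}"
            ) from None
    return pd.Series(out, index=col.index, dtype=float)


def write_ct_table(ct: CtMatrix, path, layout: str = "long", *, sep: str = ",") -> None:
    """Write a CtMatrix back to delimited text (inverse of the reader)."""
    if layout == "wide":
        out = ct.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep)
        return
    if layout != "long":
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    records = []
    ann = ct.annotations
    for g in ct.genes:
        for s in ct.samples:
            rec = {"gene": g, "sample": s, "ct": ct.values.at[g, s]}
            for c in ann.columns:
                rec[c] = ann.at[s, c]
            records.append(rec)
    pd.DataFrame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Replicate aggregation and the Ct -> quantity transform
# ---------------------------------------------------------------------------


def aggregate_technical_replicates(
    ct: CtMatrix,
    key: Sequence[str] = ("organ", "species", "replicate"),
    method: str = "mean",
    *,
    qc_spread: float = 0.5,
) -> CtMatrix:
    """Collapse technical replicates into one sample per biological unit.

    ``key`` names the annotation fields that identify a biological
    unit; samples sharing all key levels are technical replicates and
    are averaged (``mean``, the default, or ``median``).  Missing
    replicates are excluded; an all-missing set stays missing.  A
    replicate spread (max − min) above ``qc_spread`` cycles emits a
    :class:`ReplicateSpreadWarning` but does not fail.
    """
    if method not in {"mean", "median"}:
        raise ValueError(f"method must be 'mean' or 'median', got {method!r}")
    key = list(key)
    for f in key:
        if f not in ct.annotations.columns:
            raise CtValidationError(f"replicate aggregation key {f!r} not in annotations")
    labels = ct.annotations[key].astype(str).agg("_".join, axis=1)
    units = list(dict.fromkeys(labels))
    agg = pd.DataFrame(np.nan, index=ct.genes, columns=units)
    new_ann = {}
    for unit in units:
        members = labels.index[labels == unit]
        block = ct.values[members]
        spread = block.max(axis=1) - block.min(axis=1)
        wide = spread[spread > qc_spread]
        for gene, sp in wide.items():
            warnings.warn(
                f"replicate spread {sp:.2f} cycles for gene {gene!r}, unit {unit!r} "
                f"exceeds QC threshold {qc_spread}",
                ReplicateSpreadWarning,
                stacklevel=2,
            )
        agg[unit] = block.mean(axis=1) if method == "mean" else block.median(axis=1)
        new_ann[unit] = ct.annotations.loc[members[0], key]
    annotations = pd.DataFrame(new_ann).T
    annotations.index = pd.Index(units)
    return CtMatrix(agg, annotations, ct.ct_window)


def to_quantities(
    ct: CtMatrix,
    efficiencies: float | Mapping[str, float] | pd.Series = 2.0,
) -> QuantityMatrix:
    """Transform Ct to relative quantities ``Q = base**(minCt − Ct)``.

    ``efficiencies`` is the fold-per-cycle amplification base, 2.0 for
    ideal doubling (the 2^−ΔCt convention used by geNorm and
    NormFinder), or a per-gene mapping of empirical bases in (1, 2.2].
    The minimum-Ct sample of each gene becomes the calibrator (Q = 1).
    """
    if isinstance(efficiencies, (int, float)):
        bases = pd.Series(float(efficiencies), index=ct.genes)
    else:
        bases = pd.Series(efficiencies, dtype=float).reindex(ct.genes)
        if bases.isna().any():
            missing = bases.index[bases.isna()].tolist()
            raise CtValidationError(f"no efficiency supplied for genes: {missing}")
    if ((bases <= 1.0) | (bases > 2.2)).any():
        bad = bases[(bases <= 1.0) | (bases > 2.2)]
        raise CtValidationError(
            f"efficiency base outside (1, 2.2]: {dict(bad)}"
        )
    all_missing = ct.values.isna().all(axis=1)
    if all_missing.any():
        raise CtValidationError(
            f"gene(s) with all Ct missing: {list(ct.values.index[all_missing])}"
        )
    min_ct = ct.values.min(axis=1)
    delta = ct.values.sub(min_ct, axis=0)  # >= 0
    q = pd.DataFrame(
        np.power(bases.to_numpy()[:, None], -delta.to_numpy()),
        index=ct.values.index,
        columns=ct.values.columns,
    )
    return QuantityMatrix(q, bases, ct.annotations.copy())


def filter_high_missing_genes(
    ct: CtMatrix, max_missing_frac: float = 0.5
) -> tuple[CtMatrix, list[str]]:
    """Drop genes missing in more than ``max_missing_frac`` of samples.

    Returns the filtered matrix and the list of excluded genes.
    Stability scores estimated from fewer than a handful of
    observations are meaningless, so such genes are excluded from
    ranking by default (callers may re-include them explicitly).
    """
    frac = ct.values.isna().mean(axis=1)
    dropped = list(ct.values.index[frac > max_missing_frac])
    if dropped:
        warnings.warn(
            f"excluding genes with >{max_missing_frac:.0%} missing Ct: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    kept = ct.values.drop(index=dropped)
    return CtMatrix(kept, ct.annotations.copy(), ct.ct_window), dropped
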