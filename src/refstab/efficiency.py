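"""Standard-curve fitting and amplification-efficiency estimation.

A ten-fold cDNA dilution series yields (log10 relative amount, Ct)
pairs; ordinary least squares of Ct on log10 amount gives a slope in
cycles per decade, from which percent amplification efficiency is

    E[%] = (10**(-1/slope) - 1) * 100

A perfectly doubling assay has slope −1/log10(2) ≈ −3.3219 and
E = 100%.  Assays are conventionally accepted when E lies in 90–110%
and the calibration R² exceeds 0.98; both limits are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "efficiency_from_slope",
    "fit_dilution_table",
    "DEFAULT_EFFICIENCY_WINDOW",
    "DEFAULT_R2_MIN",
]

DEFAULT_EFFICIENCY_WINDOW = (90.0, 110.0)
DEFAULT_R2_MIN = 0.98


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    Strictly decreasing in |slope|: more cycles per tenfold dilution
    means lower per-cycle amplification.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass
class StandardCurve:
    """OLS fit of Ct on log10 relative template amount."""

    points: list[tuple[float, float]]  # (log10 amount, Ct)
    slope: float  # cycles per log10 unit, < 0
    intercept: float  # cycles
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return efficiency_from_slope(self.slope)

    @property
    def base(self) -> float:
        """Fold-per-cycle amplification base, 1 + E/100."""
        return 1.0 + self.efficiency_percent / 100.0

    def passes_qc(
        self,
        efficiency_window: tuple[float, float] = DEFAULT_EFFICIENCY_WINDOW,
        r2_min: float = DEFAULT_R2_MIN,
    ) -> bool:
        lo, hi = efficiency_window
        return lo <= self.efficiency_percent <= hi and self.r_squared > r2_min


def fit_standard_curve(points) -> StandardCurve:
    """Fit a dilution series of ≥3 distinct levels by OLS.

    ``points`` is an iterable of (log10 relative amount, Ct) pairs,
    e.g. amounts 0, −1, −2 for a tenfold series.  A non-negative
    fitted slope indicates assay failure and raises.
    """
    pts = [(float(x), float(y)) for x, y in points]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise ValueError(
            f"standard curve needs >=3 distinct dilution levels, got {len(levels)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4f} is non-negative: no amplification trend"
        )
    return StandardCurve(pts, float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def fit_dilution_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit one standard curve per gene from a tidy dilution table.

    Expects columns ``gene``, ``dilution_log10``, ``ct``; returns a
    per-gene report with slope, intercept, R², efficiency percent and
    a QC pass flag (columns mirroring a typical primer-validation
    table).
    """
    required = {"gene", "dilution_log10", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"dilution table needs columns {sorted(required)}")
    rows = []
    for gene, block in df.groupby("gene", sort=False):
        curve = fit_standard_curve(zip(block["dilution_log10"], block["ct"]))
        rows.append(
            {
                "gene": gene,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "efficiency_percent": curve.efficiency_percent,
                "qc_pass": curve.passes_qc(),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
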