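"""Calibration-curve alkaloid quantification, mineral element content
and element–alkaloid correlation analysis.

Alkaloids (peimisine, imperialine, peiminine, peimine) are quantified
against linear standard calibration curves, signal = slope * conc +
intercept, fitted by ordinary least squares on the standards; sample
solution concentrations (µg/mL) convert to tissue content (µg/g) via
the extraction bookkeeping

    content = conc_solution * extract_volume_mL * dilution / sample_mass_g,

with defaults matching 1.2 mL of 70 % methanol per 0.1 g of bulb
powder.  Signals at or below the curve intercept report 0 µg/g with a
below-LOD flag.

Mineral element content from a microwave-digestion / ICP-MS record
follows the national-standard formula

    X [mg/kg] = (C - C0) * V * 1000 * f / (m * 1000)

with C, C0 the sample and blank solution concentrations (mg/L), V the
digest constant volume (mL), f the dilution multiple and m the sample
weight (g).

Element–alkaloid association uses pairwise Pearson (default) or
Spearman correlation with two-sided p-values, the conventional
significance stars, and optional Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "DigestRecord",
    "CorrelationResult",
    "fit_calibration",
    "quantify",
    "element_content",
    "correlate_panels",
]


@dataclass
class CalibrationCurve:
    """Linear signal <-> concentration map for one analyte."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple  # (min, max) calibrated concentration, µg/mL
    negative_slope: bool = False

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("R^2 must be in [0, 1]")


def fit_calibration(concentrations, signals, analyte: str = "") -> CalibrationCurve:
    """OLS line through the standards: signal = slope * conc + intercept."""
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.size != s.size or c.size < 3:
        raise ValueError("need at least 3 (concentration, signal) standards")
    if np.unique(c).size < 2:
        raise ValueError("standards need at least 2 distinct concentrations")
    fit = stats.linregress(c, s)
    neg = fit.slope < 0
    if neg:
        warnings.warn(f"negative calibration slope for {analyte or 'analyte'}", stacklevel=2)
    return CalibrationCurve(
        analyte, float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
        (float(c.min()), float(c.max())), negative_slope=neg,
    )


@dataclass
class QuantResult:
    """Tissue content with unit bookkeeping and quality flags."""

    analyte: str
    content_ug_per_g: float
    conc_solution_ug_per_mL: float
    flags: list = field(default_factory=list)


def quantify(
    signal: float,
    curve: CalibrationCurve,
    extract_volume_mL: float = 1.2,
    sample_mass_g: float = 0.1,
    dilution: float = 1.0,
) -> QuantResult:
    """Invert the calibration curve and convert to µg/g of tissue.

    Flags: ``below-LOD`` when the inverted solution concentration is
    <= 0 (content reported as exactly 0); ``out-of-range`` when it
    falls outside the calibrated concentration range.
    """
    if extract_volume_mL <= 0 or sample_mass_g <= 0 or dilution <= 0:
        raise ValueError("volume, mass and dilution must be positive")
    conc = (signal - curve.intercept) / curve.slope
    flags = []
    if conc <= 0:
        return QuantResult(curve.analyte, 0.0, float(conc), ["below-LOD"])
    lo, hi = curve.conc_range
    if not lo <= conc <= hi:
        flags.append("out-of-range")
    content = conc * extract_volume_mL * dilution / sample_mass_g
    return QuantResult(curve.analyte, float(content), float(conc), flags)


@dataclass
class DigestRecord:
    """One microwave-digestion / ICP-MS measurement."""

    element: str
    C_mg_per_L: float       # element concentration in the sample solution
    C0_mg_per_L: float      # reagent-blank concentration
    V_mL: float             # digest constant volume
    f: float = 1.0          # dilution multiple
    mass_g: float = 0.2     # sample weight

    def __post_init__(self):
        if self.V_mL <= 0 or self.mass_g <= 0:
            raise ValueError("digest volume and sample mass must be positive")
        if self.f < 1:
            raise ValueError("dilution multiple must be >= 1")
        if self.C_mg_per_L < 0 or self.C0_mg_per_L < 0:
            raise ValueError("concentrations must be non-negative")


def element_content(rec: DigestRecord) -> float:
    """Element content X = (C - C0) * V * 1000 * f / (m * 1000) in mg/kg.

    A blank exceeding the sample (C < C0) yields a negative value,
    which is flagged with a warning rather than clipped.
    """
    x = (rec.C_mg_per_L - rec.C0_mg_per_L) * rec.V_mL * 1000.0 * rec.f / (rec.mass_g * 1000.0)
    if x < 0:
        warnings.warn(
            f"blank exceeds sample for {rec.element or 'element'}: content {x:g} mg/kg",
            stacklevel=2,
        )
    return float(x)


@dataclass
class CorrelationResult:
    """Element x alkaloid correlation table with p-values and stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    method: str
    adjusted: bool
    flagged: list = field(default_factory=list)  # zero-variance columns


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_panels(elements, alkaloids, method: str = "pearson",
                     adjust: bool = False) -> CorrelationResult:
    """Pairwise element-alkaloid correlations with two-sided p-values.

    ``elements`` / ``alkaloids`` may be panel objects (with a
    ``.values`` DataFrame) or plain DataFrames over matched samples.
    Zero-variance columns give NaN correlations and are listed in
    ``flagged``.  ``adjust=True`` applies Benjamini-Hochberg to the
    whole p-value table before the stars are assigned.
    """
    E = elements.values if hasattr(elements, "below_lod") else elements
    A = alkaloids.values if hasattr(alkaloids, "below_lod") else alkaloids
    E, A = pd.DataFrame(E), pd.DataFrame(A)
    if len(E) != len(A):
        raise ValueError("element and alkaloid panels have different sample counts")
    if len(E) < 4:
        raise ValueError("need at least 4 matched samples")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    r = pd.DataFrame(np.nan, index=E.columns, columns=A.columns)
    p = r.copy()
    flagged = []
    for e in E.columns:
        for a in A.columns:
            x, y = E[e].to_numpy(float), A[a].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                flagged.append((e, a))
                continue
            res = corr(x, y)
            r.loc[e, a], p.loc[e, a] = float(res.statistic), float(res.pvalue)
    padj = p.copy()
    if adjust:
        mask = ~p.isna()
        flat = p.to_numpy()[mask.to_numpy()]
        adj = stats.false_discovery_control(flat)
        out = p.to_numpy().copy()
        out[mask.to_numpy()] = adj
        padj = pd.DataFrame(out, index=p.index, columns=p.columns)
    stars = padj.map(_stars)
    return CorrelationResult(r, padj, stars, method, adjust, flagged)
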