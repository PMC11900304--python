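"""Peak integration, IS-ratio calibration and back-calculation.

Calibration fits a weighted least-squares line through (nominal
concentration, analyte/IS response ratio) points; the default 1/x²
weighting is the bioanalytical convention for ranges spanning several
orders of magnitude.  The internal standard doubles as a volumetric
anchor: because the curve is built with the IS at a fixed concentration,
a strip extract's back-calculated concentration converts to an absolute
amount through the known IS amount, independent of the extraction
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "ConversionFactor",
    "QuantResult",
    "integrate_peak",
    "response_ratio",
    "fit_calibration",
    "quantify",
    "amount_from_extract",
    "estimate_conversion_factor",
    "strip_volume",
]

Weighting = Literal["none", "1/x", "1/x2"]


def integrate_peak(
    times: np.ndarray, intensities: np.ndarray, window: tuple[float, float]
) -> float:
    """Trapezoidal peak area above a median-estimated baseline.

    The baseline is the median intensity *outside* the retention-time
    window (robust to the peak itself); the result is floored at zero.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.shape != intensities.shape or times.ndim != 1:
        raise ValueError("times and intensities must be matching 1-D arrays")
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy start < end")
    inside = (times >= lo) & (times <= hi)
    if not inside.any():
        raise ValueError("window contains no trace points")
    outside = ~inside
    baseline = float(np.median(intensities[outside])) if outside.any() else 0.0
    area = float(np.trapezoid(intensities[inside] - baseline, times[inside]))
    return max(area, 0.0)


def response_ratio(analyte_area: float, is_area: float) -> float:
    """Analyte/IS peak-area ratio; the unit of all calibration."""
    if is_area <= 0:
        raise ValueError(
            f"internal-standard area must be positive (got {is_area}); sample unusable"
        )
    if analyte_area < 0:
        raise ValueError("analyte area must be >= 0")
    return analyte_area / is_area


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted IS-ratio calibration line for one protein."""

    protein: str
    levels: tuple[tuple[float, float], ...]  # (nominal µg/mL, response ratio)
    weighting: Weighting
    slope: float
    intercept: float
    accuracy_percent: tuple[float, ...]  # back-calculated / nominal × 100, per level

    @property
    def lower(self) -> float:
        return self.levels[0][0]

    @property
    def upper(self) -> float:
        return self.levels[-1][0]


_WEIGHT_FUNCS = {
    "none": lambda x: np.ones_like(x),
    "1/x": lambda x: 1.0 / x,
    "1/x2": lambda x: 1.0 / x**2,
}


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    weighting: Weighting = "1/x2",
    protein: str = "",
) -> CalibrationCurve:
    """Weighted least-squares line through calibration points.

    ``levels`` are (nominal concentration, response ratio) pairs with
    strictly increasing concentrations; at least 5 levels are required.
    Back-calculated accuracy (100 × estimated / nominal) is reported per
    level.  Exact linear input reproduces slope/intercept to machine
    precision regardless of weighting.
    """
    if len(levels) < 5:
        raise ValueError(f"need at least 5 calibration levels, got {len(levels)}")
    if weighting not in _WEIGHT_FUNCS:
        raise ValueError(f"unknown weighting {weighting!r}")
    conc = np.array([c for c, _ in levels], dtype=float)
    ratio = np.array([r for _, r in levels], dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("nominal concentrations must be strictly increasing")
    if weighting != "none" and np.any(conc <= 0):
        raise ValueError(f"{weighting} weighting requires positive concentrations")
    w = _WEIGHT_FUNCS[weighting](conc)
    # Closed-form weighted simple regression.
    sw = w.sum()
    xbar = (w * conc).sum() / sw
    ybar = (w * ratio).sum() / sw
    sxx = (w * (conc - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate design: concentrations collapse under weighting")
    slope = float((w * (conc - xbar) * (ratio - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    if slope <= 0:
        raise ValueError(f"calibration for {protein or 'protein'} has non-positive slope")
    back = (ratio - intercept) / slope
    accuracy = tuple(float(a) for a in 100.0 * back / conc)
    return CalibrationCurve(
        protein=protein,
        levels=tuple((float(c), float(r)) for c, r in levels),
        weighting=weighting,
        slope=slope,
        intercept=intercept,
        accuracy_percent=accuracy,
    )


@dataclass(frozen=True)
class QuantResult:
    """A back-calculated concentration with range flags."""

    concentration_ug_per_ml: float
    clamped: bool = False       # raw estimate was negative, reported as 0
    extrapolated: bool = False  # above the top calibration level


def quantify(ratio: float, curve: CalibrationCurve) -> QuantResult:
    """Invert the calibration line for one response ratio."""
    if ratio < 0:
        raise ValueError("response ratio must be >= 0")
    conc = (ratio - curve.intercept) / curve.slope
    clamped = conc < 0
    if clamped:
        conc = 0.0
    return QuantResult(
        concentration_ug_per_ml=float(conc),
        clamped=clamped,
        extrapolated=conc > curve.upper,
    )


def amount_from_extract(
    extract_conc_ug_per_ml: float,
    is_amount_ug: float,
    curve_is_ug_per_ml: float,
) -> float:
    """Absolute amount (µg) on the strip from a back-calculated extract
    concentration, using the IS as the volumetric anchor.

    The curve assumes the IS at ``curve_is_ug_per_ml``; a strip carrying
    ``is_amount_ug`` of IS therefore maps concentration to amount by the
    ratio of the two, with no dependence on the extraction volume.
    """
    if is_amount_ug <= 0 or curve_is_ug_per_ml <= 0:
        raise ValueError("IS amount and curve IS concentration must be positive")
    return extract_conc_ug_per_ml * is_amount_ug / curve_is_ug_per_ml


@dataclass(frozen=True)
class ConversionFactor:
    """Wetted-length-per-volume slope of a Schirmer strip (mm/µL)."""

    estimate_mm_per_ul: float
    sd_mm_per_ul: float
    volumes_ul: tuple[float, ...] = field(default=())
    n_observations: int = 0

    def __post_init__(self) -> None:
        if self.estimate_mm_per_ul <= 0:
            raise ValueError("conversion factor must be positive")
        if self.sd_mm_per_ul < 0:
            raise ValueError("SD must be >= 0")


def estimate_conversion_factor(
    volumes_ul: Sequence[float], lengths_mm: Sequence[float]
) -> ConversionFactor:
    """Least-squares slope through the origin of length vs volume.

    A dry strip has zero wetted length, so the line is constrained
    through the origin.  The reported SD is the spread (ddof=1) of the
    per-observation length/volume ratios, matching the 'ratio ± SD'
    presentation of strip-grading practice.
    """
    v = np.asarray(volumes_ul, dtype=float)
    l = np.asarray(lengths_mm, dtype=float)
    if v.shape != l.shape or v.ndim != 1:
        raise ValueError("volumes and lengths must be matching 1-D arrays")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    distinct = np.unique(v)
    if distinct.size < 3:
        raise ValueError(f"need >= 3 distinct volumes, got {distinct.size}")
    slope = float((v * l).sum() / (v * v).sum())
    ratios = l / v
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return ConversionFactor(
        estimate_mm_per_ul=slope,
        sd_mm_per_ul=sd,
        volumes_ul=tuple(float(x) for x in distinct),
        n_observations=int(v.size),
    )


def strip_volume(length_mm: float, factor: ConversionFactor | float) -> float:
    """Tear volume (µL) adsorbed by a strip with the given wetted length."""
    if length_mm < 0:
        raise ValueError("length must be >= 0")
    f = factor.estimate_mm_per_ul if isinstance(factor, ConversionFactor) else float(factor)
    if f <= 0:
        raise ValueError("conversion factor must be positive")
    return length_mm / f
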