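"""Calibration and assay-validation utilities for the quantification step.

Matrix-matched linear calibration (response = slope * concentration +
intercept), inversion of responses back to concentrations, detection limits
from signal-to-noise (LOD at S/N 3, LLOQ at S/N 10), and precision expressed
as a coefficient of variation. Raw chromatographic signals are out of scope:
the baseline noise standard deviation is supplied by the analyst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "AssayLimits",
    "fit_calibration",
    "limits_from_snr",
    "precision_summary",
]


@dataclass(frozen=True)
class CalibrationCurve:
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def predict_response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def invert(self, response: float) -> float:
        """Concentration corresponding to an instrument response."""
        if self.slope == 0:
            raise ValueError("cannot invert a zero-slope calibration")
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class AssayLimits:
    lod: float
    lloq: float
    intraday_cv_percent: float | None = None
    interday_cv_percent: float | None = None

    def __post_init__(self) -> None:
        if not self.lod < self.lloq:
            raise ValueError("LOD must be below LLOQ")


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    weighting: Literal[None, "1/x"] = None,
) -> CalibrationCurve:
    """Least-squares line through calibration standards.

    Unweighted by default; ``"1/x"`` weights each standard by the inverse of
    its concentration (common when the calibrated range spans decades, so
    low standards are not swamped by the high end). The reported r_squared
    is the unweighted coefficient of determination of the fitted line.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and responses must have equal length")
    if x.size < 3:
        raise ValueError("calibration requires at least 3 standards")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be strictly positive")
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration: all standards at one concentration")
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    # weighted normal equations for a straight line
    W = w / w.sum()
    xbar = float(np.sum(W * x))
    ybar = float(np.sum(W * y))
    slope = float(np.sum(W * (x - xbar) * (y - ybar)) / np.sum(W * (x - xbar) ** 2))
    intercept = ybar - slope * xbar
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        concentrations=tuple(float(v) for v in x),
        responses=tuple(float(v) for v in y),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )


def limits_from_snr(noise_sd: float, curve: CalibrationCurve) -> AssayLimits:
    """Detection limits from baseline noise: LOD = 3*sd/slope, LLOQ = 10*sd/slope."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if curve.slope <= 0:
        raise ValueError("limits require a positive calibration slope")
    return AssayLimits(
        lod=3.0 * noise_sd / curve.slope,
        lloq=10.0 * noise_sd / curve.slope,
    )


def precision_summary(replicates: Sequence[float]) -> float:
    """Coefficient of variation (%) of replicate determinations: 100*sd/mean."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise ValueError("precision requires n >= 2 replicates")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("CV undefined at zero mean")
    return 100.0 * float(arr.std(ddof=1)) / mean
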