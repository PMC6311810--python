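"""BMI-based optimal contact-pressure calibration.

The piezoresistive probe must be pressed onto the radial artery with a
subject-specific force: too little and the pulse excursion is small, too
much and the waveform distorts.  The optimal pressure (OP) correlates with
body mass index, a proxy for soft-tissue thickness over the artery, and is
modelled by a fitted cubic

    OP(BMI) = -0.0114 BMI^3 + 0.7302 BMI^2 - 15.0889 BMI + 104.4144  [N]

valid on BMI in [16, 30] and approximately linear below 24.  This module
also implements the sweep-analysis protocol that produced such a curve:
median-filter the film-pressure series to obtain a baseline, pick the force
level with the largest pulsatile excursion, and fit a third-order
polynomial of OP against BMI across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ParameterError, RangeError

__all__ = [
    "OP_COEFFICIENTS",
    "SubjectProfile",
    "OpCurve",
    "compute_bmi",
    "optimal_pressure",
    "fit_baseline",
    "select_optimal_level",
    "fit_op_curve",
]

# Cubic coefficients in descending degree, newtons as a function of BMI.
OP_COEFFICIENTS = (-0.0114, 0.7302, -15.0889, 104.4144)

OP_BMI_RANGE = (16.0, 30.0)
OP_SATURATION_BMI = 24.0


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) divided by height (m) squared."""
    if weight <= 0 or height <= 0:
        raise ParameterError("weight and height must be positive")
    return weight / height**2


def optimal_pressure(
    bmi: float, valid_range: tuple[float, float] = OP_BMI_RANGE
) -> float:
    """Optimal sensor contact force in newtons for a given BMI.

    Evaluates the calibration cubic.  Above BMI 24 the curve saturates and
    loses its linear BMI dependence, so a warning is emitted there; BMIs
    outside ``valid_range`` raise :class:`RangeError`.
    """
    lo, hi = valid_range
    if not lo <= bmi <= hi:
        raise RangeError(f"BMI {bmi} outside calibration range [{lo}, {hi}]")
    if bmi > OP_SATURATION_BMI:
        warnings.warn(
            f"BMI {bmi} above {OP_SATURATION_BMI}: OP curve saturates here",
            stacklevel=2,
        )
    return float(np.polyval(OP_COEFFICIENTS, bmi))


@dataclass
class SubjectProfile:
    """A subject's anthropometrics with derived BMI and optimal pressure."""

    weight: float
    height: float
    op: Optional[float] = None

    def __post_init__(self) -> None:
        self.bmi = compute_bmi(self.weight, self.height)
        if self.op is not None and not 0 < self.op <= 14:
            raise ParameterError("op must lie in (0, 14] N")

    @classmethod
    def from_bmi(cls, bmi: float, op: Optional[float] = None) -> "SubjectProfile":
        """Build a profile from BMI alone (unit height)."""
        return cls(weight=bmi, height=1.0, op=op)


@dataclass
class OpCurve:
    """Cubic OP-vs-BMI curve with fit diagnostics."""

    coefficients: np.ndarray  # descending degree, 4 entries
    fit_domain: tuple[float, float]
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ParameterError("OpCurve requires exactly 4 coefficients")
        if not self.fit_domain[0] < self.fit_domain[1]:
            raise ParameterError("fit_domain must be a non-empty interval")

    def __call__(self, bmi) -> np.ndarray:
        return np.polyval(self.coefficients, bmi)


def fit_baseline(pressure_series: Sequence[float], window: int) -> np.ndarray:
    """Running-median baseline of a film-pressure series.

    Edge samples are handled by replicating the end values so the output
    has the same length as the input.
    """
    series = np.asarray(pressure_series, dtype=float)
    if window % 2 == 0:
        raise ParameterError("median window must be odd")
    if not 1 <= window <= len(series):
        raise ParameterError("median window must lie in [1, len(series)]")
    return median_filter(series, size=window, mode="nearest")


def select_optimal_level(
    sweep: pd.DataFrame, window: int = 5
) -> tuple[float, float]:
    """Pick the force level with the largest pulsatile excursion.

    The per-level samples are concatenated in level order, a running-median
    baseline is fitted, and the sample maximizing |pressure - baseline| is
    located; ties break toward the lower level.  Returns ``(level,
    baseline_value)`` where the baseline value is the calibrated optimal
    pressure for the subject.
    """
    if len(sweep) < 2:
        raise ParameterError("sweep must contain at least 2 levels")
    sample_cols = [c for c in sweep.columns if c.startswith("sample_")]
    if not sample_cols:
        raise ParameterError("sweep has no sample columns")
    levels = sweep["level_N"].to_numpy(dtype=float)
    samples = sweep[sample_cols].to_numpy(dtype=float)  # (n_levels, n_samples)
    flat = samples.ravel()
    baseline = fit_baseline(flat, window)
    idx = int(np.argmax(np.abs(flat - baseline)))  # argmax keeps the first, i.e.
    level_idx = idx // samples.shape[1]             # the lower level, on ties
    return float(levels[level_idx]), float(baseline[idx])


def fit_op_curve(
    bmis: Sequence[float], op_values: Sequence[float]
) -> OpCurve:
    """Least-squares cubic fit of optimal pressure against BMI."""
    x = np.asarray(bmis, dtype=float)
    y = np.asarray(op_values, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("bmis and op_values must have equal length")
    if len(np.unique(x)) < 4:
        raise ParameterError("need at least 4 distinct BMI values for a cubic fit")
    # Polynomial.fit works in a scaled domain for conditioning, then the
    # coefficients are converted back to the raw BMI axis.
    poly = np.polynomial.Polynomial.fit(x, y, deg=3).convert()
    coeffs_desc = poly.coef[::-1]
    if len(coeffs_desc) < 4:  # degenerate leading terms dropped by convert()
        coeffs_desc = np.concatenate(
            [np.zeros(4 - len(coeffs_desc)), coeffs_desc]
        )
    residuals = np.polyval(coeffs_desc, x) - y
    return OpCurve(
        coefficients=coeffs_desc,
        fit_domain=(float(x.min()), float(x.max())),
        residuals=residuals,
    )
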