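"""Closed-form assay arithmetic.

Covers the bench calculations around the fermentation work: titratable
acidity from an NaOH titration (total acid expressed as lactic acid via the
conversion coefficient k = 0.090), the DNS reducing-sugar standard curve
with inverse prediction, the apparent adsorption amount of an ion-exchange
resin, and fold changes between log-scale viable counts.

All operations are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TitrationMeasurement",
    "StandardCurve",
    "AdsorptionRecord",
    "titratable_acidity",
    "fit_dns_curve",
    "glucose_from_absorbance",
    "apparent_adsorption",
    "fold_change_from_lg",
    "display_fold",
]


@dataclass(frozen=True)
class TitrationMeasurement:
    """One acid-base titration of a fermentation supernatant.

    c: NaOH concentration (mol/L); v1/v0: titrant volumes for the sample
    and the blank (mL); k: lactic acid conversion coefficient (g/mmol,
    0.090 for lactic acid); v: sample volume (mL).
    """

    c: float
    v1: float
    v0: float
    v: float
    k: float = 0.090

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("NaOH concentration must be positive")
        if self.v <= 0:
            raise ValueError("sample volume must be positive")
        if not self.v1 >= self.v0 >= 0:
            raise ValueError("need titrant volumes v1 >= v0 >= 0")


def titratable_acidity(m: TitrationMeasurement) -> float:
    """Total acid as lactic acid, g/L: P = c (V1 - V0) k / V * 1000."""
    return m.c * (m.v1 - m.v0) * m.k / m.v * 1000.0


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares absorbance-versus-concentration line."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be nonzero for inversion")

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


def fit_dns_curve(concentrations: Sequence[float],
                  absorbances: Sequence[float]) -> StandardCurve:
    """Fit the DNS standard curve (absorbance at 540 nm vs glucose, mg/mL).

    Ordinary least squares on >= 3 calibration points with distinct
    concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and absorbances must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations are all identical")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         conc_min=float(x.min()), conc_max=float(x.max()))


def glucose_from_absorbance(curve: StandardCurve, absorbance: float) -> float:
    """Invert the standard curve: concentration = (A - intercept) / slope.

    Predictions outside the calibration range are returned but logged as
    extrapolations.
    """
    import logging

    conc = (absorbance - curve.intercept) / curve.slope
    if not curve.conc_min <= conc <= curve.conc_max:
        logging.getLogger(__name__).warning(
            "inverse prediction %.4g mg/mL lies outside the calibration "
            "range [%.4g, %.4g]", conc, curve.conc_min, curve.conc_max)
    return conc


def apparent_adsorption(dose: float, delta_c: float) -> float:
    """Apparent adsorption amount q = (C0 - C) / dose.

    ``dose`` is the resin usage (g/L) and ``delta_c`` the adsorbed lactic
    acid C0 - C (g/L), so q is grams of lactic acid per gram of resin.
    """
    if dose <= 0:
        raise ValueError("resin dose must be positive (q is undefined at dose 0)")
    return delta_c / dose


def fold_change_from_lg(lg_new: float, lg_ref: float) -> float:
    """Fold change between two base-10 log counts: 10**(lg_new - lg_ref)."""
    if not (math.isfinite(lg_new) and math.isfinite(lg_ref)):
        raise ValueError("log counts must be finite")
    return 10.0 ** (lg_new - lg_ref)


def display_fold(fold: float, decimals: int = 1) -> float:
    """Round a fold change for display (one decimal by convention)."""
    return round(fold, decimals)


@dataclass(frozen=True)
class AdsorptionRecord:
    """A (dose, adsorbed amount) pair with its derived q."""

    dose: float
    delta_c: float

    @property
    def q(self) -> float:
        return apparent_adsorption(self.dose, self.delta_c)
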