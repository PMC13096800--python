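"""First-order photoconversion kinetics.

A photoprobe depleted by irradiation follows pseudo-first-order photolysis:
the remaining fraction after dose D (J/cm^2, intensity x time) is
``exp(-k*D)`` with a single rate constant k per unit dose. Conversion is
therefore a function of dose alone (reciprocity), the time to reach a target
conversion scales inversely with intensity, and the fold-acceleration between
two light sources at a fixed conversion target equals their intensity ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IrradiationRegime",
    "PhotoKineticModel",
    "conversion",
    "time_to_conversion",
    "fold_acceleration",
    "fit_rate",
]


@dataclass(frozen=True)
class IrradiationRegime:
    """Constant-intensity exposure: intensity in W/cm^2, duration in s."""

    intensity: float
    duration: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def dose(self) -> float:
        """Delivered dose in J/cm^2."""
        return self.intensity * self.duration


@dataclass(frozen=True)
class PhotoKineticModel:
    """First-order photoconversion: rate constant per unit dose, (J/cm^2)^-1."""

    rate_per_dose: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.rate_per_dose <= 0:
            raise ValueError("rate_per_dose must be > 0")


def conversion(model: PhotoKineticModel, regime: IrradiationRegime) -> float:
    """Converted fraction after the regime: 1 - exp(-k * I * t)."""
    return 1.0 - math.exp(-model.rate_per_dose * regime.dose)


def time_to_conversion(
    model: PhotoKineticModel, intensity: float, target: float
) -> float:
    """Seconds of exposure at ``intensity`` to reach a target conversion < 1."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    if not 0 < target < 1:
        raise ValueError("target conversion must lie in (0, 1)")
    return -math.log(1.0 - target) / (model.rate_per_dose * intensity)


def fold_acceleration(t_slow: float, t_fast: float) -> float:
    """Ratio of exposure times reaching the same conversion, t_slow / t_fast."""
    if t_slow <= 0 or t_fast <= 0:
        raise ValueError("exposure times must be > 0")
    return t_slow / t_fast


def fit_rate(
    timepoints: np.ndarray,
    remaining_fraction: np.ndarray,
    intensity: float,
) -> PhotoKineticModel:
    """Fit the per-dose rate from a probe-depletion time course.

    OLS of ln(remaining fraction) on dose; the rate is minus the slope. The
    coefficient of determination of the log-linear fit is reported on the
    model.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(remaining_fraction, dtype=float)
    if t.shape != f.shape or t.size < 2:
        raise ValueError("need >= 2 matching (time, fraction) points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("remaining fractions must lie in (0, 1]")
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    dose = intensity * t
    y = np.log(f)
    slope, intercept = np.polyfit(dose, y, 1)
    fitted = slope * dose + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        raise ValueError("depletion curve has non-negative slope; no decay")
    return PhotoKineticModel(rate_per_dose=-float(slope), r_squared=r2)
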