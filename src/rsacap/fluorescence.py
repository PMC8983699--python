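"""Fluorescence-depletion quantification of captured particles.

A film is immersed in a fluorescently labelled particle dispersion; the
drop in solution fluorescence before vs after immersion, read through a
linear calibration curve, gives the captured concentration.  Total captured
mass is ``m_tot = Δc · V``; for monodisperse particles the count follows as
``N = m_tot / m_particle`` with the single-particle sphere mass.  For
heterogeneous particles (e.g. polydisperse polyethylene) only the mass is
reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rsa_model import ParticleSpec, particle_mass

__all__ = [
    "DEFAULT_STANDARDS_G_L",
    "CalibrationCurve",
    "DepletionMeasurement",
    "fit_calibration",
    "concentration_from_intensity",
    "captured_particles",
    "captured_mass",
    "area_to_remove_all",
]

#: Standard concentration series for calibration (g L^-1).
DEFAULT_STANDARDS_G_L = (0.0, 0.025, 0.05, 0.075, 0.1)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration calibration."""

    concentrations: tuple
    intensities: tuple
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("a valid fluorophore calibration has slope > 0")


@dataclass
class DepletionMeasurement:
    """Triplicate before/after fluorescence readings for one film."""

    intensity_before: np.ndarray
    intensity_after: np.ndarray
    volume_ml: float
    particle: ParticleSpec
    film_area_cm2: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        self.intensity_before = np.atleast_1d(
            np.asarray(self.intensity_before, dtype=float))
        self.intensity_after = np.atleast_1d(
            np.asarray(self.intensity_after, dtype=float))
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")
        if self.intensity_before.size < 1 or self.intensity_after.size < 1:
            raise ValueError("need at least one reading per condition")


def fit_calibration(concentrations, intensities) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, intensity).

    Requires at least three standards; the blank (c = 0) is an ordinary
    standard, so the line keeps a free intercept.
    """
    c = np.asarray(concentrations, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.ptp(c) == 0:
        raise ValueError("standards must span more than one concentration")
    res = stats.linregress(c, i)
    return CalibrationCurve(
        concentrations=tuple(c),
        intensities=tuple(i),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def concentration_from_intensity(curve: CalibrationCurve, intensity):
    """Invert the calibration: c = (I - intercept) / slope, floored at 0."""
    i = np.asarray(intensity, dtype=float)
    c = (i - curve.intercept) / curve.slope
    if np.any(c < 0):
        # round-off at exactly-blank readings is not worth a warning
        if np.any(c < -1e-9):
            warnings.warn(
                "intensity below blank: concentration clipped to 0",
                stacklevel=2)
        c = np.clip(c, 0.0, None)
    return c.item() if np.isscalar(intensity) else c


def _depletion_stats(measurement: DepletionMeasurement,
                     curve: CalibrationCurve) -> tuple[float, float]:
    """Mean and SD of the captured concentration Δc (g L^-1)."""
    c_before = concentration_from_intensity(
        curve, measurement.intensity_before)
    c_after = concentration_from_intensity(
        curve, measurement.intensity_after)
    c_before = np.atleast_1d(c_before)
    c_after = np.atleast_1d(c_after)
    mean_dc = float(c_before.mean() - c_after.mean())
    var = 0.0
    if c_before.size > 1:
        var += c_before.var(ddof=1) / c_before.size
    if c_after.size > 1:
        var += c_after.var(ddof=1) / c_after.size
    return mean_dc, math.sqrt(var)


def captured_mass(measurement: DepletionMeasurement,
                  curve: CalibrationCurve,
                  noise_tolerance: float = 3.0) -> tuple[float, float]:
    """Captured mass m_tot = Δc · V in ng, with propagated SD.

    Δc in g L^-1 times V in mL gives mg; converted to ng (1 mg = 1e6 ng).
    Negative depletion within ``noise_tolerance`` standard deviations is
    clipped to zero; beyond it, an error is raised.
    """
    mean_dc, sd_dc = _depletion_stats(measurement, curve)
    if mean_dc < 0:
        if sd_dc > 0 and -mean_dc > noise_tolerance * sd_dc:
            raise ValueError(
                "after-immersion concentration exceeds before beyond noise")
        mean_dc = 0.0
    to_ng = measurement.volume_ml * 1e6  # (g/L * mL) = mg -> ng
    return mean_dc * to_ng, sd_dc * to_ng


def captured_particles(measurement: DepletionMeasurement,
                       curve: CalibrationCurve,
                       noise_tolerance: float = 3.0) -> tuple[float, float]:
    """Number of captured particles N = Δc·V / m_particle, with SD.

    Valid for monodisperse spheres only; the single-particle mass comes
    from the measurement's :class:`ParticleSpec` (sphere volume times
    density, default 1.05 g cm^-3 for polystyrene).
    """
    mass_ng, sd_ng = captured_mass(measurement, curve, noise_tolerance)
    m_p = particle_mass(measurement.particle)
    return mass_ng / m_p, sd_ng / m_p


def area_to_remove_all(total: float, capture_per_area: float) -> float:
    """Film area (cm^2) needed to capture everything, rounded up.

    ``total`` and ``capture_per_area`` may be particle counts or masses, as
    long as they share units (``capture_per_area`` per cm^2).
    """
    if capture_per_area <= 0:
        raise ValueError("capture rate per area must be positive")
    if total <= 0:
        return 0.0
    return float(math.ceil(total / capture_per_area))
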