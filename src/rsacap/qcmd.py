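"""QCM-D trace processing: Sauerbrey mass, rescaling and coupled water.

A quartz crystal microbalance with dissipation monitoring (QCM-D) reports
frequency shifts ``Δf_n`` and dissipation shifts ``ΔD_n`` at odd overtones
n of a 5 MHz crystal.  For a rigid film the Sauerbrey relation converts
frequency to areal mass,

    Δm = -(C / n) Δf,      C = 17.7 ng cm^-2 Hz^-1,

valid only while dissipation stays low (< 1e-5).  Adsorbed particle layers
carry acoustically coupled water, so the QCM-D mass overestimates the dry
particle mass; dividing the measured frequency shift by the shift implied
by the image-analysis dry mass gives the coupled-water factor.  This module
also assembles the per-system coverage summary (dry and hydrated coverages,
fractional coverage against the jamming limit, occupied-area diameter).

A critical convention: instrument exports may report Δf either raw or
divided by the overtone number.  The normalization is always declared
explicitly, never guessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .rsa_model import (
    THETA_INF,
    CoverageSummary,
    ParticleSpec,
    d_rsa_from_area,
    effective_area,
    NM2_TO_CM2,
)

__all__ = [
    "Normalization",
    "SensorSpec",
    "QCMDTrace",
    "sauerbrey_mass",
    "dissipation_flag",
    "rescale_to_dry_mass",
    "coupled_water_factor",
    "coverage_solid_air",
    "fractional_coverage",
    "sensor_total_mass",
    "build_coverage_summary",
]

logger = logging.getLogger(__name__)

ODD_OVERTONES = (1, 3, 5, 7, 9, 11)

#: Sauerbrey validity threshold on |ΔD| (dissipation units, not x1e-6).
DISSIPATION_LIMIT = 1e-5


class Normalization(str, Enum):
    """Frequency-shift convention of a trace."""

    raw = "raw"
    normalized_by_n = "normalized_by_n"


@dataclass(frozen=True)
class SensorSpec:
    """AT-cut quartz sensor constants."""

    sauerbrey_C: float = 17.7   # ng cm^-2 Hz^-1
    sensor_diameter: float = 9.0  # mm
    fundamental: float = 5.0    # MHz

    def __post_init__(self) -> None:
        if min(self.sauerbrey_C, self.sensor_diameter, self.fundamental) <= 0:
            raise ValueError("sensor constants must be positive")

    @property
    def area_cm2(self) -> float:
        return math.pi * (self.sensor_diameter / 20.0) ** 2  # mm -> cm


@dataclass
class QCMDTrace:
    """Per-overtone QCM-D time series.

    ``data`` holds columns ``time_s`` plus ``f{n}`` (Hz) and ``D{n}``
    (dissipation units x1e-6) for the overtones present.
    """

    data: pd.DataFrame
    normalization: Normalization
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.normalization = Normalization(self.normalization)
        if "time_s" not in self.data.columns:
            raise ValueError("trace must have a time_s column")
        t = self.data["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.overtones:
            raise ValueError("trace has no frequency channels")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def overtones(self) -> list[int]:
        return sorted(int(c[1:]) for c in self.data.columns
                      if c.startswith("f") and c[1:].isdigit())

    def delta_f(self, n: int) -> np.ndarray:
        self._check_overtone(n)
        return self.data[f"f{n}"].to_numpy()

    def delta_D(self, n: int) -> np.ndarray:
        self._check_overtone(n)
        col = f"D{n}"
        if col not in self.data.columns:
            raise KeyError(f"dissipation channel {col} missing")
        return self.data[col].to_numpy()

    def _check_overtone(self, n: int) -> None:
        if n % 2 == 0:
            raise ValueError("QCM-D overtones are odd")
        if f"f{n}" not in self.data.columns:
            raise KeyError(f"overtone {n} not in trace")

    def endpoint_delta_f(self, n: int, window_s: float = 60.0) -> float:
        """Mean Δf over the final window (robust post-rinse endpoint)."""
        t = self.time
        sel = t >= t[-1] - window_s
        return float(self.delta_f(n)[sel].mean())


def sauerbrey_mass(delta_f, n: int, sensor: SensorSpec = SensorSpec(),
                   normalization: Normalization | str = Normalization.raw):
    """Convert a frequency shift to areal mass via the Sauerbrey relation.

    Raw shifts are divided by the overtone number; shifts already
    normalized by n are multiplied by C directly, so both conventions give
    identical mass.

    Parameters
    ----------
    delta_f : float or array_like
        Frequency shift in Hz (negative for mass uptake).
    n : int
        Odd overtone number.
    normalization : Normalization
        Convention of ``delta_f``; must be declared.

    Returns
    -------
    float or ndarray
        Areal mass in ng cm^-2 (positive for negative Δf).
    """
    if n % 2 == 0 or n < 1:
        raise ValueError("overtone number must be odd and positive")
    normalization = Normalization(normalization)
    f = np.asarray(delta_f, dtype=float)
    if normalization is Normalization.raw:
        out = -(sensor.sauerbrey_C / n) * f
    else:
        out = -sensor.sauerbrey_C * f
    return out.item() if np.isscalar(delta_f) else out


def dissipation_flag(trace: QCMDTrace, n: int = 5,
                     limit: float = DISSIPATION_LIMIT) -> bool:
    """True iff the dissipation stays within the Sauerbrey validity band.

    ΔD channels are stored in units of 1e-6, so the default limit of 1e-5
    corresponds to 10 in stored units.  A False return flags the layer as
    soft/hydrated: Sauerbrey mass then reports hydrated, not dry, mass.
    """
    dd = trace.delta_D(n)
    return bool(np.max(np.abs(dd)) * 1e-6 < limit)


def rescale_to_dry_mass(mass_series, gamma_max_ia: float):
    """Rescale a hydrated QCM-D mass series to the image-analysis dry mass.

    ``Gamma(t) = m(t) * (Gamma_max / max m(t))``: the whole series is
    multiplied by one factor so its maximum equals the dry surface mass
    density from particle counting.  This removes the acoustically coupled
    water from the trace under the assumption that hydration is
    proportional to particle load.
    """
    m = np.asarray(mass_series, dtype=float)
    peak = m.max()
    if peak <= 0:
        raise ValueError("mass series must have a positive maximum")
    if gamma_max_ia <= 0:
        raise ValueError("dry surface mass density must be positive")
    return m * (gamma_max_ia / peak)


def coupled_water_factor(delta_f_qcm: float, gamma_ia: float, n: int = 5,
                         sensor: SensorSpec = SensorSpec(),
                         normalization: Normalization | str = Normalization.raw
                         ) -> tuple[float, float]:
    """Hydrated/dry mass ratio from QCM-D vs image-analysis frequency shifts.

    The dry mass implies a theoretical raw shift ``Δf_n(IA) = -Γ_IA n / C``;
    the measured raw shift divided by it is the coupled-water factor (>= 1
    when water is sensed along with the particles).

    Parameters
    ----------
    delta_f_qcm : float
        Measured frequency shift at overtone ``n`` (convention declared by
        ``normalization``).
    gamma_ia : float
        Dry surface mass density from image analysis (ng cm^-2).

    Returns
    -------
    (factor, factor_rounded)
        The unrounded ratio and its 1-decimal presentation value.
    """
    if gamma_ia <= 0:
        raise ValueError("gamma_ia must be positive")
    if n % 2 == 0:
        raise ValueError("overtone number must be odd")
    normalization = Normalization(normalization)
    f_raw = delta_f_qcm if normalization is Normalization.raw \
        else delta_f_qcm * n
    delta_f_ia = -gamma_ia * n / sensor.sauerbrey_C
    if f_raw * delta_f_ia <= 0:
        raise ValueError("QCM and image-analysis shifts must share a sign")
    factor = f_raw / delta_f_ia
    return factor, round(factor, 1)


def coverage_solid_air(gamma_ia: float, m: float,
                       spec: ParticleSpec) -> float:
    """Dry (solid/air) fractional coverage from the image-analysis mass.

    ``theta_air = (Gamma_IA / m) * pi (d_eff / 2)^2`` — the particle number
    density times the effective cross-sectional area.
    """
    if m <= 0:
        raise ValueError("particle mass must be positive")
    if gamma_ia < 0:
        raise ValueError("gamma must be non-negative")
    return (gamma_ia / m) * effective_area(spec) * NM2_TO_CM2


def fractional_coverage(theta_air: float,
                        theta_inf: float = THETA_INF) -> float:
    """Coverage as a fraction of the RSA jamming limit."""
    if theta_inf <= 0:
        raise ValueError("theta_inf must be positive")
    return theta_air / theta_inf


def sensor_total_mass(gamma: float,
                      sensor: SensorSpec = SensorSpec()) -> float:
    """Total adsorbed mass on the sensor face, Γ x sensor area (ng)."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return gamma * sensor.area_cm2


def build_coverage_summary(label: str,
                           delta_f5: float,
                           delta_D5: float,
                           gamma_max_ia: float,
                           a_nm2: float,
                           k_a: float,
                           m: float,
                           spec: ParticleSpec,
                           normalization: Normalization | str,
                           sensor: SensorSpec = SensorSpec(),
                           theta_inf: float = THETA_INF) -> CoverageSummary:
    """Assemble the full per-system coverage record.

    Combines the QCM-D endpoint (Δf5, ΔD5), the image-analysis dry mass,
    and the fitted kinetic parameters (a, k_a) into the summary holding
    hydration factor, solid/air and solid/liquid coverages, occupied-area
    diameter and fractional coverage.
    """
    if gamma_max_ia == 0 and delta_f5 == 0:
        return CoverageSummary(label=label, theta_inf=theta_inf)
    water, _ = coupled_water_factor(delta_f5, gamma_max_ia, n=5,
                                    sensor=sensor,
                                    normalization=normalization)
    theta_air = coverage_solid_air(gamma_max_ia, m, spec)
    # Solid/liquid coverage uses the fitted occupied area (particle plus
    # coupled water): theta = Gamma a / m.
    theta_liquid = gamma_max_ia * a_nm2 * NM2_TO_CM2 / m
    summary = CoverageSummary(
        label=label,
        delta_f5=delta_f5,
        delta_D5=delta_D5,
        gamma_max=gamma_max_ia,
        theta_air=theta_air,
        theta_liquid=theta_liquid,
        a_nm2=a_nm2,
        d_rsa=d_rsa_from_area(a_nm2),
        k_a=k_a,
        water_factor=water,
        fractional_coverage=fractional_coverage(theta_air, theta_inf),
        theta_inf=theta_inf,
    )
    logger.info("coverage summary %s: water=%.2f theta_air=%.3g "
                "theta_liquid=%.3g", label, water, theta_air, theta_liquid)
    return summary


def summary_frame(summaries: list[CoverageSummary]) -> pd.DataFrame:
    """Tabulate coverage summaries in the canonical column order."""
    rows = []
    for s in summaries:
        rows.append({
            "system": s.label,
            "delta_f5_Hz": s.delta_f5,
            "delta_D5_1e6": s.delta_D5,
            "coupled_water": round(s.water_factor, 1),
            "gamma_max_ng_cm2": s.gamma_max,
            "theta_air": float(f"{s.theta_air:.2g}"),
            "theta_liquid": float(f"{s.theta_liquid:.2g}"),
            "a_1e4_nm2": s.a_nm2 / 1e4,
            "d_rsa_nm": float(f"{s.d_rsa:.2g}"),
            "k_a_1e-5_cm_s": s.k_a / 1e-5,
            "fractional_coverage": float(f"{s.fractional_coverage:.2g}"),
        })
    return pd.DataFrame(rows)
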