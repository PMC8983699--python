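"""Closed-form random sequential adsorption (RSA) mathematics.

Equal hard disks adsorbing irreversibly on a plane saturate at the jamming
coverage ``theta_inf ≈ 0.547``.  The rate at which new disks attach is
proportional to the surface blocking function ``B(theta)`` — the probability
that a uniformly random insertion attempt at coverage ``theta`` is accepted.
This module provides the low-coverage virial expansion of ``B``, the
near-jamming asymptote, single-particle geometry (mass, effective area,
packing counts) and the forward integration of the adsorption rate equation

    dGamma/dt = k_a * c * B(Gamma * a / m)

for the surface mass density ``Gamma(t)`` (ng cm^-2), with adsorption rate
coefficient ``k_a`` (cm s^-1), bulk mass concentration ``c`` (ng cm^-3),
occupied area per particle ``a`` and single-particle mass ``m``.

Internal unit system: ng, cm, s, Hz.  Areas given in nm^2 at the public
boundary are converted (1 nm^2 = 1e-14 cm^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "THETA_INF",
    "K0_NEAR_JAMMING",
    "NM2_TO_CM2",
    "Regime",
    "ParticleSpec",
    "RSAKinetics",
    "CoverageSummary",
    "blocking_function",
    "blocking_function_near_jamming",
    "surface_coverage",
    "particle_mass",
    "effective_area",
    "max_packing_count",
    "d_rsa_from_area",
    "regime_crossover",
    "integrate_rsa_kinetics",
]

#: Jamming coverage of equal hard disks under RSA.
THETA_INF = 0.547

#: Prefactor of the near-jamming blocking asymptote B = K0 (theta_inf - theta)^3.
K0_NEAR_JAMMING = 8.98

#: nm^2 -> cm^2
NM2_TO_CM2 = 1e-14

# Virial coefficients of the low-coverage expansion of B(theta)
_B2 = 6.0 * math.sqrt(3.0) / math.pi
_B3 = 40.0 / (math.pi * math.sqrt(3.0)) - 176.0 / (3.0 * math.pi**2)

#: Coverage above which the cubic expansion is no longer quantitatively valid.
POLY_VALIDITY_LIMIT = 0.3


class Regime(str, Enum):
    """Which blocking function drives the kinetic integration."""

    low_coverage_polynomial = "low_coverage_polynomial"
    near_jamming = "near_jamming"
    blended = "blended"


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of a model plastic particle.

    Parameters
    ----------
    diameter_abs : float
        Absolute (nominal) particle diameter in nm.
    density : float
        Particle density in g cm^-3.
    eff_factor : float
        Multiplier inflating the diameter to the effective diameter used in
        packing calculations (accounts for the electrical double layer and
        hydration shell). Default 1.1.
    label : str
        Free-text label.
    """

    diameter_abs: float
    density: float = 1.05
    eff_factor: float = 1.1
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_abs <= 0:
            raise ValueError("diameter_abs must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.eff_factor < 1:
            raise ValueError("eff_factor must be >= 1")

    @property
    def diameter_eff(self) -> float:
        """Effective diameter in nm."""
        return self.eff_factor * self.diameter_abs

    @property
    def mass_ng(self) -> float:
        """Single-particle mass in ng (sphere of the absolute diameter)."""
        return particle_mass(self)

    @property
    def area_eff_nm2(self) -> float:
        """Effective cross-sectional area in nm^2."""
        return effective_area(self)


@dataclass
class RSAKinetics:
    """Parameter set of the RSA adsorption rate equation.

    Attributes
    ----------
    k_a : float
        Adsorption rate coefficient (cm s^-1).
    a_nm2 : float
        Occupied area per adsorbed particle, including strongly coupled
        water (nm^2).
    m : float
        Single-particle mass (ng).
    c : float
        Bulk mass concentration (ng cm^-3); ``c = c' * m`` with ``c'`` the
        number concentration.
    theta_inf : float
        Jamming coverage. Default 0.547.
    K0 : float
        Near-jamming blocking prefactor. Default 8.98.
    regime : Regime
        Blocking-function regime for the integration. Desorption is fixed at
        zero: adsorption is treated as irreversible.
    """

    k_a: float
    a_nm2: float
    m: float
    c: float
    theta_inf: float = THETA_INF
    K0: float = K0_NEAR_JAMMING
    regime: Regime = Regime.blended
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_a < 0:
            raise ValueError("k_a must be non-negative")
        if self.a_nm2 <= 0:
            raise ValueError("a must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if not (0 < self.theta_inf <= 1):
            raise ValueError("theta_inf must lie in (0, 1]")
        if self.K0 <= 0:
            raise ValueError("K0 must be positive")
        self.regime = Regime(self.regime)

    @property
    def a_cm2(self) -> float:
        """Occupied area per particle in cm^2."""
        return self.a_nm2 * NM2_TO_CM2

    @property
    def ka_c(self) -> float:
        """Composite initial adsorption rate k_a * c (ng cm^-2 s^-1)."""
        return self.k_a * self.c

    @property
    def a_over_m(self) -> float:
        """Composite coverage conversion a / m (cm^2 ng^-1)."""
        return self.a_cm2 / self.m

    @property
    def gamma_jam(self) -> float:
        """Surface mass density at jamming, theta_inf * m / a (ng cm^-2)."""
        return self.theta_inf / self.a_over_m


@dataclass
class CoverageSummary:
    """Derived coverage quantities for one substrate/particle pair.

    Mirrors the columns of a coverage-summary table: maximum surface mass
    density from image analysis, coverages at the solid/air and solid/liquid
    interfaces, fitted area per particle and its circular-equivalent
    diameter, adsorption rate coefficient, coupled-water factor and the
    fractional coverage theta_air / theta_inf.
    """

    label: str = ""
    delta_f5: float = 0.0
    delta_D5: float = 0.0
    gamma_max: float = 0.0
    theta_air: float = 0.0
    theta_liquid: float = 0.0
    a_nm2: float = 0.0
    d_rsa: float = 0.0
    k_a: float = 0.0
    water_factor: float = 0.0
    fractional_coverage: float = 0.0
    theta_inf: float = THETA_INF

    def validate(self, rtol: float = 0.05) -> None:
        """Check internal consistency (d_rsa vs a, fractional vs theta_air)."""
        for name in ("gamma_max", "theta_air", "theta_liquid", "a_nm2",
                     "d_rsa", "k_a", "water_factor", "fractional_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a_nm2 > 0:
            d_expected = d_rsa_from_area(self.a_nm2)
            if not math.isclose(self.d_rsa, d_expected, rel_tol=rtol):
                raise ValueError(
                    f"d_rsa={self.d_rsa} inconsistent with a={self.a_nm2} "
                    f"(expected {d_expected:.1f})"
                )
        if self.theta_air > 0:
            frac = self.theta_air / self.theta_inf
            if not math.isclose(self.fractional_coverage, frac, rel_tol=rtol):
                raise ValueError(
                    "fractional_coverage inconsistent with theta_air/theta_inf"
                )


def blocking_function(theta):
    """Low-coverage surface blocking function of RSA for equal disks.

    ``B(theta) = 1 - 4 theta + (6 sqrt 3 / pi) theta^2
    + (40/(pi sqrt 3) - 176/(3 pi^2)) theta^3``

    Quantitatively valid for ``theta < 0.3``; evaluation outside
    ``[0, theta_inf]`` is rejected because the truncated series turns
    unphysical there.

    Parameters
    ----------
    theta : float or array_like
        Fractional surface coverage, ``0 <= theta <= 0.547``.

    Returns
    -------
    float or ndarray
        Acceptance probability of a random insertion attempt.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise ValueError("coverage must be non-negative")
    if np.any(th > THETA_INF):
        raise ValueError(
            f"cubic blocking expansion not defined above theta={THETA_INF}"
        )
    out = 1.0 - 4.0 * th + _B2 * th**2 + _B3 * th**3
    return out.item() if np.isscalar(theta) else out


def blocking_function_near_jamming(theta, theta_inf: float = THETA_INF,
                                   K0: float = K0_NEAR_JAMMING):
    """Near-jamming asymptote of the blocking function.

    ``B(theta) = K0 (theta_inf - theta)^3``, vanishing exactly at jamming.

    Parameters
    ----------
    theta : float or array_like
        Fractional coverage, must not exceed ``theta_inf``.
    theta_inf : float
        Jamming coverage (default 0.547).
    K0 : float
        Prefactor (default 8.98).
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th > theta_inf):
        raise ValueError("coverage exceeds the jamming limit")
    out = K0 * (theta_inf - th) ** 3
    return out.item() if np.isscalar(theta) else out


def surface_coverage(gamma, a_nm2: float, m: float):
    """Fractional coverage from surface mass density: theta = Gamma a / m.

    Parameters
    ----------
    gamma : float or array_like
        Surface mass density (ng cm^-2).
    a_nm2 : float
        Occupied area per particle (nm^2).
    m : float
        Single-particle mass (ng).

    Warns when the result exceeds 0.3, where the linear relation underlying
    the low-coverage kinetics loses validity.
    """
    if a_nm2 <= 0:
        raise ValueError("a must be positive")
    if m <= 0:
        raise ValueError("m must be positive")
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be non-negative")
    theta = g * (a_nm2 * NM2_TO_CM2) / m
    if np.any(theta > POLY_VALIDITY_LIMIT):
        warnings.warn(
            "coverage exceeds 0.3: low-coverage kinetics not valid here",
            stacklevel=2,
        )
    return theta.item() if np.isscalar(gamma) else theta


def particle_mass(spec: ParticleSpec) -> float:
    """Mass of a spherical particle in ng.

    ``m = rho * (4/3) pi (d_abs/2)^3`` with the absolute diameter; the
    effective diameter only enters packing geometry, not mass.
    """
    r_cm = spec.diameter_abs * 1e-7 / 2.0  # nm -> cm
    volume_cm3 = 4.0 / 3.0 * math.pi * r_cm**3
    return spec.density * volume_cm3 * 1e9  # g -> ng


def effective_area(spec: ParticleSpec) -> float:
    """Cross-sectional area pi (d_eff/2)^2 of one particle in nm^2."""
    return math.pi * (spec.diameter_eff / 2.0) ** 2


def max_packing_count(area_mm2: float, spec: ParticleSpec,
                      theta_inf: float = THETA_INF) -> float:
    """Maximum number of particles an area can hold at the jamming coverage.

    ``N_max = theta_inf * area / A_particle`` with the effective
    cross-sectional area.  Returned as a real number; callers may floor.
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    area_nm2 = area_mm2 * 1e12  # mm^2 -> nm^2
    return theta_inf * area_nm2 / effective_area(spec)


def d_rsa_from_area(a_nm2: float) -> float:
    """Diameter (nm) of the circle of area ``a``: d = 2 sqrt(a / pi)."""
    if a_nm2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(a_nm2 / math.pi)


def regime_crossover(theta_inf: float = THETA_INF,
                     K0: float = K0_NEAR_JAMMING,
                     tol: float = 1e-10) -> float:
    """Coverage where the cubic expansion meets the near-jamming asymptote.

    The two blocking expressions intersect slightly above 0.3 for the
    standard constants; the blended kinetic regime switches between them at
    this point so the rate equation's right-hand side stays continuous.
    Located by scanning (0.29, theta_inf) for the first sign change and
    polishing with Brent's method.
    """

    def diff(th: float) -> float:
        return (1.0 - 4.0 * th + _B2 * th**2 + _B3 * th**3
                - K0 * (theta_inf - th) ** 3)

    grid = np.linspace(0.29, theta_inf - 1e-9, 400)
    vals = np.array([diff(t) for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        # No intersection: fall back to the point of closest approach.
        return float(grid[np.argmin(np.abs(vals))])
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1], xtol=tol))


def _make_rhs(params: RSAKinetics):
    """Right-hand side of dGamma/dt for the chosen regime."""
    ka_c = params.ka_c
    a_over_m = params.a_over_m
    theta_inf = params.theta_inf
    K0 = params.K0
    regime = params.regime

    if regime is Regime.blended:
        theta_x = regime_crossover(theta_inf, K0)
    else:
        theta_x = None

    def rhs(t, y):
        theta = y[0] * a_over_m
        if theta >= theta_inf:
            return [0.0]
        if regime is Regime.near_jamming:
            b = K0 * (theta_inf - theta) ** 3
        elif regime is Regime.low_coverage_polynomial:
            b = 1.0 - 4.0 * theta + _B2 * theta**2 + _B3 * theta**3
            b = max(b, 0.0)  # truncated series dips below 0 near 0.47
        else:
            if theta < theta_x:
                b = 1.0 - 4.0 * theta + _B2 * theta**2 + _B3 * theta**3
            else:
                b = K0 * (theta_inf - theta) ** 3
        return [ka_c * b]

    return rhs, theta_x


def integrate_rsa_kinetics(params: RSAKinetics,
                           time_grid: Sequence[float],
                           rtol: float = 1e-8,
                           atol: float = 1e-10) -> np.ndarray:
    """Integrate the RSA rate equation for the surface mass density.

    Solves ``dGamma/dt = k_a c B(Gamma a / m)`` from ``Gamma(0) = 0`` on the
    given time grid with an adaptive stiff-capable solver (LSODA).  The
    blocking function is chosen per ``params.regime``; in the blended regime
    the cubic expansion is used below the crossover coverage and the
    near-jamming asymptote above it.

    Parameters
    ----------
    params : RSAKinetics
    time_grid : array_like
        Monotone non-decreasing times in s, starting at 0.
    rtol, atol : float
        Solver tolerances (atol in ng cm^-2).

    Returns
    -------
    ndarray
        Gamma(t) in ng cm^-2, same length as ``time_grid``.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if t[0] != 0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be monotone non-decreasing")
    if t.size == 1:
        return np.zeros(1)

    rhs, _ = _make_rhs(params)
    sol = solve_ivp(rhs, (0.0, float(t[-1])), [0.0], t_eval=t,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"RSA kinetics integration failed: {sol.message}")
    # Guard against tiny solver overshoot of the jamming fixed point and
    # enforce monotonicity at the tolerance floor.
    gamma = np.clip(sol.y[0], 0.0, params.gamma_jam)
    return np.maximum.accumulate(gamma)
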