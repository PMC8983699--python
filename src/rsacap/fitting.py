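"""Nonlinear least-squares fitting of RSA adsorption kinetics.

The measured (rescaled, dry) surface mass density Gamma(t) is fitted with
the integrated RSA rate equation

    dGamma/dt = k_a c B(Gamma a / m),   Gamma(0) = 0,

over the two composite coefficients ``k_a c`` (initial rate, ng cm^-2 s^-1)
and ``a / m`` (coverage conversion, cm^2 ng^-1).  Knowing the bulk
concentration c and the single-particle mass m de-composites these into the
adsorption rate coefficient ``k_a`` (cm s^-1) and the occupied area per
particle ``a`` (nm^2, particle plus strongly coupled water).

The interface follows the Model/Results idiom: build an
:class:`RSAAdsorptionModel` from the data, call :meth:`fit`, inspect the
returned :class:`RSAAdsorptionResults` (params, standard errors,
adjusted R^2, residuals, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rsa_model import (
    THETA_INF,
    K0_NEAR_JAMMING,
    NM2_TO_CM2,
    Regime,
    RSAKinetics,
    integrate_rsa_kinetics,
)

__all__ = ["RSAAdsorptionModel", "RSAAdsorptionResults",
           "adjusted_r_squared"]


def adjusted_r_squared(observed, fitted, n_params: int) -> float:
    """Adjusted coefficient of determination.

    ``1 - (1 - R^2)(N - 1)/(N - p - 1)`` with ``p`` fitted parameters.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    n = len(y)
    if n < n_params + 2:
        raise ValueError("need at least n_params + 2 observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observations have zero variance")
    ss_res = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


class RSAAdsorptionModel:
    """RSA kinetic model bound to one rescaled adsorption trace.

    Parameters
    ----------
    time : array_like
        Timestamps in s; the objective is evaluated on these, unresampled.
    gamma : array_like
        Dry surface mass density Gamma(t) in ng cm^-2, starting near 0.
    concentration : float
        Bulk mass concentration c in ng cm^-3 (0.1 g L^-1 = 1e5).
    particle_mass : float
        Single-particle mass m in ng.
    regime : Regime or str
        Blocking-function regime used during integration (default blended).
    theta_inf, K0 : float
        Jamming coverage and near-jamming prefactor.
    bounds : tuple
        (lower, upper) bounds applied to both composite coefficients in the
        internal ng/cm/s unit system. Default (0, 10).
    """

    n_params = 2

    def __init__(self, time, gamma, concentration: float,
                 particle_mass: float,
                 regime: Regime | str = Regime.blended,
                 theta_inf: float = THETA_INF,
                 K0: float = K0_NEAR_JAMMING,
                 bounds: tuple[float, float] = (0.0, 10.0)):
        self.time = np.asarray(time, dtype=float)
        self.gamma = np.asarray(gamma, dtype=float)
        if self.time.shape != self.gamma.shape or self.time.ndim != 1:
            raise ValueError("time and gamma must be 1-D and equal length")
        if len(self.time) < self.n_params + 2:
            raise ValueError("too few observations to fit")
        if concentration <= 0 or particle_mass <= 0:
            raise ValueError("concentration and particle mass must be > 0")
        self.concentration = float(concentration)
        self.particle_mass = float(particle_mass)
        self.regime = Regime(regime)
        self.theta_inf = theta_inf
        self.K0 = K0
        self.bounds = bounds
        # The solver grid must start at 0 with Gamma(0)=0.
        if self.time[0] != 0:
            self._t_solver = np.concatenate([[0.0], self.time])
            self._prepend = True
        else:
            self._t_solver = self.time
            self._prepend = False

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, concentration: float,
                       particle_mass: float, time_col: str = "time_s",
                       gamma_col: str = "gamma", **kwargs
                       ) -> "RSAAdsorptionModel":
        return cls(df[time_col].to_numpy(), df[gamma_col].to_numpy(),
                   concentration, particle_mass, **kwargs)

    # -- forward model -----------------------------------------------------

    def _kinetics(self, ka_c: float, a_over_m: float) -> RSAKinetics:
        """Composite coefficients -> physical parameter set."""
        a_nm2 = a_over_m * self.particle_mass / NM2_TO_CM2
        return RSAKinetics(
            k_a=ka_c / self.concentration,
            a_nm2=a_nm2,
            m=self.particle_mass,
            c=self.concentration,
            theta_inf=self.theta_inf,
            K0=self.K0,
            regime=self.regime,
        )

    def predict(self, params, time=None) -> np.ndarray:
        """Integrated Gamma(t) for composite params (ka_c, a_over_m)."""
        ka_c, a_over_m = params
        if time is None:
            t, prepend = self._t_solver, self._prepend
        else:
            t = np.asarray(time, dtype=float)
            prepend = t[0] != 0
            if prepend:
                t = np.concatenate([[0.0], t])
        if ka_c == 0:
            out = np.zeros_like(t)
        else:
            out = integrate_rsa_kinetics(self._kinetics(ka_c, a_over_m), t)
        return out[1:] if prepend else out

    def _residuals(self, params) -> np.ndarray:
        return self.predict(params) - self.gamma

    # -- estimation --------------------------------------------------------

    def fit(self, start: float = 0.1, n_starts: int = 5,
            loss: str = "linear") -> "RSAAdsorptionResults":
        """Trust-region least squares over the composite coefficients.

        Both coefficients start at ``start`` (default 0.1) with bounds from
        the model.  ``n_starts > 1`` adds log-spaced multistarts around the
        nominal start to guard against the flat likelihood near jamming;
        the best (lowest-cost) converged solution wins.

        Parameters
        ----------
        start : float
            Nominal starting value of both composites.
        n_starts : int
            Number of starting points (1 = the paper-style single start).
        loss : str
            scipy.optimize.least_squares loss ("linear" or "soft_l1").
        """
        lo, hi = self.bounds
        starts = [np.array([start, start])]
        if n_starts > 1:
            factors = np.logspace(-1.5, 1.5, n_starts - 1)
            for fct in factors:
                s = np.clip(start * fct, lo + 1e-12, hi)
                starts.append(np.array([s, s]))

        best = None
        for x0 in starts:
            sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                                method="trf", loss=loss, x_scale="jac")
            if best is None or (sol.success and sol.cost < best.cost):
                best = sol
        if best is None or not best.success:
            raise RuntimeError("RSA fit did not converge from any start")

        fitted = self.predict(best.x)
        resid = self.gamma - fitted
        # Gauss-Newton covariance of the composites.
        J = best.jac
        dof = max(len(self.gamma) - self.n_params, 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            bse = np.full(2, np.nan)

        eps = 1e-9 * (hi - lo)
        bounds_hit = bool(np.any(best.x <= lo + eps) or
                          np.any(best.x >= hi - eps))
        return RSAAdsorptionResults(
            model=self,
            params=best.x,
            bse=bse,
            cov_params=cov,
            fittedvalues=fitted,
            resid=resid,
            cost=float(best.cost),
            nfev=int(best.nfev),
            bounds_hit=bounds_hit,
            n_starts=len(starts),
        )


@dataclass
class RSAAdsorptionResults:
    """Fit results: composite coefficients, physical parameters, diagnostics.

    ``params`` holds (k_a·c, a/m) in ng cm^-2 s^-1 and cm^2 ng^-1; the
    physical ``k_a`` (cm s^-1) and ``a_nm2`` (nm^2) follow from the bulk
    concentration and particle mass carried by the model.
    """

    model: RSAAdsorptionModel
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    fittedvalues: np.ndarray
    resid: np.ndarray
    cost: float
    nfev: int
    bounds_hit: bool
    n_starts: int
    extra: dict = field(default_factory=dict)

    @property
    def ka_c(self) -> float:
        return float(self.params[0])

    @property
    def a_over_m(self) -> float:
        return float(self.params[1])

    @property
    def k_a(self) -> float:
        """Adsorption rate coefficient, cm s^-1."""
        return self.ka_c / self.model.concentration

    @property
    def a_nm2(self) -> float:
        """Occupied area per particle (incl. coupled water), nm^2."""
        return self.a_over_m * self.model.particle_mass / NM2_TO_CM2

    @property
    def k_a_se(self) -> float:
        return float(self.bse[0]) / self.model.concentration

    @property
    def a_nm2_se(self) -> float:
        return float(self.bse[1]) * self.model.particle_mass / NM2_TO_CM2

    @property
    def adjusted_r2(self) -> float:
        return adjusted_r_squared(self.model.gamma, self.fittedvalues,
                                  self.model.n_params)

    @property
    def gamma_jam(self) -> float:
        """Jamming plateau implied by the fit, theta_inf / (a/m)."""
        return self.model.theta_inf / self.a_over_m

    def predict(self, time=None) -> np.ndarray:
        return self.model.predict(self.params, time=time)

    def to_dict(self) -> dict:
        return {
            "ka_c": self.ka_c,
            "a_over_m": self.a_over_m,
            "k_a_cm_s": self.k_a,
            "a_nm2": self.a_nm2,
            "k_a_se": self.k_a_se,
            "a_nm2_se": self.a_nm2_se,
            "adjusted_r2": self.adjusted_r2,
            "regime": self.model.regime.value,
            "bounds_hit": self.bounds_hit,
            "n_starts": self.n_starts,
            "nfev": self.nfev,
        }

    def summary(self) -> str:
        """Plain-text parameter table."""
        d = self.to_dict()
        lines = [
            "RSA adsorption kinetics fit",
            "=" * 46,
            f"observations      {len(self.model.gamma):>12d}",
            f"regime            {d['regime']:>12s}",
            f"adjusted R^2      {d['adjusted_r2']:>12.4f}",
            f"function evals    {d['nfev']:>12d}",
            "-" * 46,
            "              estimate     std err",
            f"k_a*c     {self.ka_c:>12.4g} {float(self.bse[0]):>11.2g}"
            "   ng/cm^2/s",
            f"a/m       {self.a_over_m:>12.4g} {float(self.bse[1]):>11.2g}"
            "   cm^2/ng",
            f"k_a       {self.k_a:>12.4g} {self.k_a_se:>11.2g}   cm/s",
            f"a         {self.a_nm2:>12.4g} {self.a_nm2_se:>11.2g}   nm^2",
            "-" * 46,
        ]
        if self.bounds_hit:
            lines.append("WARNING: solution pinned at a parameter bound")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay data and fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.time, self.model.gamma, ".", ms=3, alpha=0.5,
                label="data")
        ax.plot(self.model.time, self.fittedvalues, "-", lw=2, label="fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"$\Gamma$ (ng cm$^{-2}$)")
        ax.legend()
        return ax
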