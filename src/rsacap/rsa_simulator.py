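"""Monte Carlo random sequential adsorption of equal hard disks.

Disks of a fixed diameter are placed one at a time at uniformly random
positions in a square box; an attempt is accepted iff the new disk overlaps
no previously accepted disk (pure steric exclusion). Coverage saturates at
the jamming limit, approached at late dimensionless time tau as

    theta(tau) = theta_inf - b * tau^(-1/2)          (Feder's law)

where tau = attempts * disk_area / box_area. The simulator serves as the
independent numerical check of the jamming constant 0.547 used throughout
the closed-form model, and supplies ground-truth particle configurations to
the synthetic image generator.

Overlap tests use a uniform grid hash with cell size equal to the disk
diameter, so each attempt inspects at most a 3x3 neighbourhood.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DepositionConfiguration",
    "simulate_rsa_deposition",
    "coverage_of_configuration",
    "estimate_jamming_coverage",
    "acceptance_rate_profile",
]

_CHUNK = 16384  # random attempts drawn per batch


@dataclass
class DepositionConfiguration:
    """Result of one RSA deposition run.

    ``centers`` holds accepted disk centres (nm); ``accept_attempts`` the
    1-based attempt index at which each was accepted, allowing coverage to
    be reconstructed as a function of attempts.
    """

    box_size: float
    disk_diameter: float
    periodic: bool
    centers: np.ndarray
    attempts_made: int
    seed: int
    accept_attempts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_disks(self) -> int:
        return len(self.centers)

    @property
    def tau(self) -> float:
        """Dimensionless time: attempts * disk area / box area."""
        disk_area = math.pi * (self.disk_diameter / 2.0) ** 2
        return self.attempts_made * disk_area / self.box_size**2

    def coverage_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(tau, theta) after each accepted disk."""
        disk_area = math.pi * (self.disk_diameter / 2.0) ** 2
        tau = self.accept_attempts * disk_area / self.box_size**2
        theta = np.arange(1, self.n_disks + 1) * disk_area / self.box_size**2
        return tau, theta

    def validate(self) -> None:
        """Assert the hard-core constraint pairwise (O(n^2); for tests)."""
        c = self.centers
        if len(c) < 2:
            return
        d = c[:, None, :] - c[None, :, :]
        if self.periodic:
            d = d - self.box_size * np.round(d / self.box_size)
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < self.disk_diameter * (1 - 1e-12):
            raise AssertionError(
                f"hard-core violation: min distance {dist.min()} < "
                f"{self.disk_diameter}")

    def to_text(self) -> str:
        """Serialize as delimited text (header + x,y per line)."""
        buf = io.StringIO()
        buf.write(f"# box_size={self.box_size} "
                  f"disk_diameter={self.disk_diameter} "
                  f"periodic={int(self.periodic)} seed={self.seed} "
                  f"attempts={self.attempts_made}\n")
        buf.write("x,y\n")
        for x, y in self.centers:
            buf.write(f"{float(x)!r},{float(y)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "DepositionConfiguration":
        lines = text.strip().splitlines()
        meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        centers = np.array(
            [[float(v) for v in ln.split(",")] for ln in lines[2:]]
        ).reshape(-1, 2)
        return cls(
            box_size=float(meta["box_size"]),
            disk_diameter=float(meta["disk_diameter"]),
            periodic=bool(int(meta["periodic"])),
            centers=centers,
            attempts_made=int(meta["attempts"]),
            seed=int(meta["seed"]),
        )


class _DiskGrid:
    """Uniform grid hash for O(1) hard-disk overlap tests."""

    def __init__(self, box_size: float, diameter: float, periodic: bool):
        self.box = box_size
        self.d2 = diameter * diameter
        self.periodic = periodic
        # Cell edge >= diameter so overlap partners lie in the 3x3 block.
        self.n_cells = max(1, int(box_size / diameter))
        self.cell = box_size / self.n_cells
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _cell_of(self, x: float, y: float) -> tuple[int, int]:
        return (min(int(x / self.cell), self.n_cells - 1),
                min(int(y / self.cell), self.n_cells - 1))

    def fits(self, x: float, y: float) -> bool:
        n = self.n_cells
        box = self.box
        cx, cy = self._cell_of(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                ix, iy = cx + dx, cy + dy
                if self.periodic:
                    ix %= n
                    iy %= n
                elif not (0 <= ix < n and 0 <= iy < n):
                    continue
                for (px, py) in self.cells.get((ix, iy), ()):
                    ddx = px - x
                    ddy = py - y
                    if self.periodic:
                        if ddx > box / 2:
                            ddx -= box
                        elif ddx < -box / 2:
                            ddx += box
                        if ddy > box / 2:
                            ddy -= box
                        elif ddy < -box / 2:
                            ddy += box
                    if ddx * ddx + ddy * ddy < self.d2:
                        return False
        return True

    def insert(self, x: float, y: float) -> None:
        self.cells.setdefault(self._cell_of(x, y), []).append((x, y))


def simulate_rsa_deposition(box_size: float,
                            disk_diameter: float,
                            max_attempts: int,
                            periodic: bool = True,
                            seed: int = 0) -> DepositionConfiguration:
    """Run sequential random deposition of equal hard disks.

    Parameters
    ----------
    box_size : float
        Side of the square domain (same length unit as the diameter).
    disk_diameter : float
        Hard-core exclusion diameter.
    max_attempts : int
        Number of uniform-random insertion attempts.
    periodic : bool
        Periodic boundaries (default); if False, centres are restricted to
        lie at least one radius from every wall (minus-sampling of
        positions) so the bulk coverage is unbiased.
    seed : int
        Seed of the underlying PCG64 generator; identical seeds give
        bit-identical configurations.

    Returns
    -------
    DepositionConfiguration
    """
    if max_attempts <= 0:
        raise ValueError("max_attempts must be positive")
    if periodic and box_size < disk_diameter:
        raise ValueError("periodic box must be at least one diameter wide")

    radius = disk_diameter / 2.0
    if not periodic and box_size < disk_diameter:
        warnings.warn("box smaller than one disk: empty configuration",
                      stacklevel=2)
        return DepositionConfiguration(
            box_size, disk_diameter, periodic,
            np.empty((0, 2)), max_attempts, seed)

    rng = np.random.default_rng(seed)
    grid = _DiskGrid(box_size, disk_diameter, periodic)
    if periodic:
        lo, span = 0.0, box_size
    else:
        lo, span = radius, box_size - disk_diameter

    centers: list[tuple[float, float]] = []
    accept_at: list[int] = []
    done = 0
    while done < max_attempts:
        n = min(_CHUNK, max_attempts - done)
        pts = lo + span * rng.random((n, 2))
        for i in range(n):
            x, y = pts[i, 0], pts[i, 1]
            if grid.fits(x, y):
                grid.insert(x, y)
                centers.append((x, y))
                accept_at.append(done + i + 1)
        done += n

    return DepositionConfiguration(
        box_size=box_size,
        disk_diameter=disk_diameter,
        periodic=periodic,
        centers=np.array(centers).reshape(-1, 2),
        attempts_made=max_attempts,
        seed=seed,
        accept_attempts=np.asarray(accept_at, dtype=np.int64),
    )


def coverage_of_configuration(config: DepositionConfiguration) -> float:
    """Fraction of the box area covered by disks.

    Disk area is not clipped at walls; in the non-periodic case the centres
    are already constrained to the interior, so total disk area divided by
    box area is the bulk coverage.
    """
    disk_area = math.pi * (config.disk_diameter / 2.0) ** 2
    return config.n_disks * disk_area / config.box_size**2


def estimate_jamming_coverage(tau: Sequence[float],
                              theta: Sequence[float],
                              tau_min: float = 50.0
                              ) -> tuple[float, float, dict]:
    """Extrapolate finite-time RSA coverage to the jamming limit.

    Fits Feder's late-time law ``theta(tau) = theta_inf - b tau^(-1/2)`` by
    linear least squares in ``x = tau^(-1/2)`` over the window
    ``tau >= tau_min``.

    Returns
    -------
    (theta_inf, stderr, diagnostics)
        Point estimate, its standard error, and a dict with the slope ``b``
        and window size.
    """
    tau = np.asarray(tau, dtype=float)
    theta = np.asarray(theta, dtype=float)
    sel = tau >= tau_min
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 points with tau >= {tau_min}; got {int(sel.sum())}")
    x = tau[sel] ** -0.5
    y = theta[sel]
    # theta = theta_inf - b x
    A = np.column_stack([np.ones_like(x), -x])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    theta_inf_hat, b = coef
    n = len(y)
    if n > 2:
        dof = n - 2
        s2 = float(res[0]) / dof if res.size else \
            float(((A @ coef - y) ** 2).sum()) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se = math.sqrt(max(cov[0, 0], 0.0))
    else:
        se = 0.0
    return float(theta_inf_hat), se, {"b": float(b), "n_points": n,
                                      "tau_min": tau_min}


def acceptance_rate_profile(config: DepositionConfiguration,
                            n_windows: int = 20,
                            theta_max: float = 0.3
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical insertion acceptance rate versus coverage.

    Splits the attempt sequence into windows and, within each, computes the
    fraction of accepted attempts and the mid-window coverage.  At low
    coverage this empirical rate estimates the blocking function B(theta),
    providing the Monte-Carlo cross-check of the closed-form cubic.

    Returns
    -------
    (theta_mid, rate, rate_se)
        Windows whose mid coverage exceeds ``theta_max`` are dropped.
    """
    disk_area = math.pi * (config.disk_diameter / 2.0) ** 2
    per_disk = disk_area / config.box_size**2
    total = config.attempts_made
    edges = np.linspace(0, total, n_windows + 1, dtype=np.int64)
    acc = config.accept_attempts

    theta_mid, rate, se = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi == lo:
            continue
        n_before = int(np.searchsorted(acc, lo, side="right"))
        n_after = int(np.searchsorted(acc, hi, side="right"))
        k = n_after - n_before
        n_att = int(hi - lo)
        th = (n_before + k / 2.0) * per_disk
        if th > theta_max:
            break
        p = k / n_att
        theta_mid.append(th)
        rate.append(p)
        se.append(math.sqrt(max(p * (1 - p), 1e-12) / n_att))
    return np.array(theta_mid), np.array(rate), np.array(se)
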