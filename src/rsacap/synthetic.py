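"""Synthetic instrument data with known ground truth.

Stands in for the lab instruments: every generator is a pure function of a
:class:`SyntheticScenario` and its seed, and returns ground truth alongside
the data so that pipeline recovery can be asserted.

* QCM-D traces — forward RSA kinetics (dry Γ(t)), multiplied by a
  coupled-water factor for hydrated mass, converted to Δf5 through the
  Sauerbrey relation (raw convention) with multiplicative Gaussian noise,
  followed by a noiseless rinse plateau.  The default scenario mirrors the
  reference experiment: 0.1 g L^-1 dispersion flowing for ~1 h, water
  factor 3.2, 2% relative noise.
* SEM-style images — bright anti-aliased disks placed by the hard-disk RSA
  simulator on a noisy dark background (Gaussian, mean 30, sd 8 on the
  8-bit scale), optional touching-triplet clusters, optional scale bar.
* Fluorescence tables — a linear intensity response over the standard
  concentration series with additive noise, plus triplicate before/after
  readings at a chosen capture fraction.

The ΔD5 channel is a proportional placeholder scaled to land in the 5–50
(x1e-6) range typical of soft particle layers; it carries no viscoelastic
physics and is only there so that dissipation QC logic has input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluorescence import DEFAULT_STANDARDS_G_L
from .qcmd import Normalization, QCMDTrace, SensorSpec
from .rsa_model import ParticleSpec, RSAKinetics, integrate_rsa_kinetics
from .rsa_simulator import simulate_rsa_deposition
from .sem import ImageRecord

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "generate_qcmd_trace",
    "generate_sem_image",
    "generate_fluorescence_dataset",
]


@dataclass
class SyntheticScenario:
    """Complete description of one simulated experiment."""

    seed: int = 0
    particle: ParticleSpec = field(
        default_factory=lambda: ParticleSpec(
            diameter_abs=100.0, density=1.005, eff_factor=1.1,
            label="PS(100nm)"))
    kinetics: RSAKinetics = field(
        default_factory=lambda: RSAKinetics(
            k_a=1.0e-5, a_nm2=6.0e4, m=5.26e-7, c=1.0e5))
    water_factor: float = 3.2
    qcmd_noise_rel: float = 0.02
    duration_s: float = 3600.0
    sample_dt_s: float = 2.0
    rinse_s: float = 600.0
    sensor: SensorSpec = field(default_factory=SensorSpec)
    # imaging
    image_shape: tuple[int, int] = (1536, 2048)  # rows, cols
    nm_per_px: float = 2.0
    background_mean: float = 30.0
    background_sd: float = 8.0
    particle_intensity: float = 200.0
    blur_sigma_px: float = 1.0
    # fluorescence
    fluor_slope: float = 8000.0   # a.u. per g L^-1
    fluor_intercept: float = 20.0  # blank signal, a.u.
    fluor_noise_sd: float = 5.0   # a.u.
    volume_ml: float = 20.0
    stock_g_l: float = 0.1

    def __post_init__(self) -> None:
        if self.water_factor < 1:
            raise ValueError("water factor must be >= 1")


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """The reference scenario; fields overridable by keyword."""
    sc = SyntheticScenario(seed=seed)
    return replace(sc, **overrides) if overrides else sc


def generate_qcmd_trace(scenario: SyntheticScenario
                        ) -> tuple[QCMDTrace, pd.DataFrame]:
    """Simulate a hydrated QCM-D adsorption trace.

    Returns the trace (raw Δf convention, overtone 5) and a ground-truth
    frame with columns ``time_s``, ``gamma_dry`` and ``gamma_hydrated``.
    The adsorption phase carries multiplicative Gaussian noise; the
    appended rinse plateau is noiseless, representing the stable post-rinse
    baseline from which endpoints are read.
    """
    rng = np.random.default_rng(scenario.seed)
    t_ads = np.arange(0.0, scenario.duration_s + scenario.sample_dt_s / 2,
                      scenario.sample_dt_s)
    gamma_dry = integrate_rsa_kinetics(scenario.kinetics, t_ads)
    gamma_hyd = gamma_dry * scenario.water_factor

    noise = 1.0 + scenario.qcmd_noise_rel * rng.standard_normal(t_ads.size)
    hyd_noisy = gamma_hyd * noise

    n_rinse = int(round(scenario.rinse_s / scenario.sample_dt_s))
    t_rinse = t_ads[-1] + scenario.sample_dt_s * np.arange(1, n_rinse + 1)
    plateau = np.full(n_rinse, gamma_hyd[-1])

    t = np.concatenate([t_ads, t_rinse])
    hyd = np.concatenate([hyd_noisy, plateau])
    C = scenario.sensor.sauerbrey_C
    f5 = -hyd * 5.0 / C  # raw Sauerbrey inversion at n = 5
    # Placeholder dissipation: proportional to hydrated load, scaled so the
    # endpoint sits in the 5-50 (x1e-6) band seen for soft particle layers.
    endpoint = max(gamma_hyd[-1], 1e-12)
    d5 = 20.0 * hyd / endpoint

    trace = QCMDTrace(
        data=pd.DataFrame({"time_s": t, "f5": f5, "D5": d5}),
        normalization=Normalization.raw,
        metadata={
            "seed": scenario.seed,
            "water_factor": scenario.water_factor,
            "substrate": "synthetic",
            "particle": scenario.particle.label,
        },
    )
    truth = pd.DataFrame({
        "time_s": t,
        "gamma_dry": np.concatenate(
            [gamma_dry, np.full(n_rinse, gamma_dry[-1])]),
        "gamma_hydrated": np.concatenate(
            [gamma_hyd, np.full(n_rinse, gamma_hyd[-1])]),
    })
    return trace, truth


def _render_disks(canvas: np.ndarray, centers: np.ndarray,
                  radius_px: float) -> None:
    """Add unit-intensity anti-aliased disks to a float canvas in place."""
    h, w = canvas.shape
    r_out = radius_px + 1.0
    for cx, cy in centers:  # x = col, y = row
        c0 = max(int(cx - r_out), 0)
        c1 = min(int(cx + r_out) + 2, w)
        r0 = max(int(cy - r_out), 0)
        r1 = min(int(cy + r_out) + 2, h)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.sqrt((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2)
        # linear anti-aliased edge over one pixel
        cover = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        np.maximum(canvas[r0:r1, c0:c1], cover,
                   out=canvas[r0:r1, c0:c1])


def generate_sem_image(scenario: SyntheticScenario,
                       target_coverage: float,
                       cluster_fraction: float = 0.0,
                       embed_scale_bar: bool = True,
                       scale_bar_nm: float = 500.0
                       ) -> tuple[ImageRecord, dict]:
    """Render an SEM-like image of RSA-deposited particles.

    Disks of the particle's effective diameter are placed by the hard-disk
    simulator until ``target_coverage`` is (approximately) reached; a
    fraction of particles may instead be laid down as touching triplets to
    exercise cluster counting.  Ground truth returns centres, the planted
    count and the realized coverage.

    ``target_coverage`` must stay below 0.5 — approaching the jamming limit
    makes placement attempts astronomically expensive.
    """
    if not 0 <= target_coverage <= 0.5:
        raise ValueError("target coverage must lie in [0, 0.5]")
    if not 0 <= cluster_fraction <= 1:
        raise ValueError("cluster fraction must lie in [0, 1]")
    rng = np.random.default_rng(scenario.seed + 1)
    h, w = scenario.image_shape
    d_px = scenario.particle.diameter_eff / scenario.nm_per_px
    r_px = d_px / 2.0
    disk_area = math.pi * r_px**2
    n_target = int(round(target_coverage * h * w / disk_area))

    centers: list[tuple[float, float]] = []
    if n_target > 0 and cluster_fraction < 1.0:
        # Non-clustered particles via an RSA run on the larger box side;
        # rejected if outside the non-square frame.
        n_singles_target = int(round(n_target * (1 - cluster_fraction)))
        box = float(max(h, w))
        attempts = max(200 * n_target, 20000)
        # Inflated exclusion diameter keeps rendered singles from touching
        # at tangency and merging after blur.
        cfg = simulate_rsa_deposition(box, 1.15 * d_px, attempts,
                                      periodic=False,
                                      seed=int(rng.integers(2**31)))
        for x, y in cfg.centers:
            if r_px <= x <= w - r_px and r_px <= y <= h - r_px:
                centers.append((x, y))
            if len(centers) >= n_singles_target:
                break
    n_singles = len(centers)

    # Touching triplets: equilateral triangle of side d, random orientation.
    n_triplets = int(round(n_target * cluster_fraction / 3.0))
    placed_triplets = 0
    guard = 0
    arr = np.array(centers).reshape(-1, 2)
    while placed_triplets < n_triplets and guard < 20000:
        guard += 1
        cx = rng.uniform(2 * d_px, w - 2 * d_px)
        cy = rng.uniform(2 * d_px, h - 2 * d_px)
        phi = rng.uniform(0, 2 * math.pi)
        tri = []
        ok = True
        for k in range(3):
            ang = phi + 2 * math.pi * k / 3
            px_ = cx + d_px / math.sqrt(3) * math.cos(ang)
            py_ = cy + d_px / math.sqrt(3) * math.sin(ang)
            if arr.size:
                dmin = np.sqrt(((arr - (px_, py_)) ** 2).sum(1)).min()
                if dmin < d_px:
                    ok = False
                    break
            tri.append((px_, py_))
        if ok:
            centers.extend(tri)
            arr = np.array(centers).reshape(-1, 2)
            placed_triplets += 1

    canvas = np.zeros((h, w))
    _render_disks(canvas, np.array(centers).reshape(-1, 2), r_px)
    if scenario.blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter
        canvas = gaussian_filter(canvas, scenario.blur_sigma_px)
    img = (scenario.background_mean
           + scenario.background_sd * rng.standard_normal((h, w))
           + scenario.particle_intensity * canvas)

    bar_bbox = None
    if embed_scale_bar:
        bar_px = int(round(scale_bar_nm / scenario.nm_per_px))
        r0, r1 = h - 30, h - 20
        c1 = w - 20
        c0 = c1 - bar_px
        img[r0:r1, c0:c1] = 255.0
        bar_bbox = (r0 - 5, c0 - 5, r1 + 5, c1 + 5)

    record = ImageRecord(
        pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
        nm_per_px=scenario.nm_per_px,
        provenance=f"synthetic(seed={scenario.seed})",
        scale_bar_bbox=bar_bbox,
    )
    truth = {
        "centers_px": np.array(centers).reshape(-1, 2),
        "n_particles": len(centers),
        "n_singles": n_singles,
        "n_triplets": placed_triplets,
        "coverage": len(centers) * disk_area / (h * w),
        "diameter_px": d_px,
        "scale_bar_nm": scale_bar_nm if embed_scale_bar else None,
        "seed": scenario.seed,
    }
    return record, truth


def generate_fluorescence_dataset(scenario: SyntheticScenario,
                                  true_capture_fraction: float,
                                  n_replicates: int = 3
                                  ) -> tuple[pd.DataFrame, pd.DataFrame,
                                             dict]:
    """Simulate calibration standards and before/after depletion readings.

    Returns (standards, readings, ground truth).  Standards use the
    canonical five-concentration series; readings are triplicate intensity
    values before and after immersion with the given capture fraction of
    the stock concentration removed.
    """
    if not 0 <= true_capture_fraction <= 1:
        raise ValueError("capture fraction must lie in [0, 1]")
    rng = np.random.default_rng(scenario.seed + 2)

    conc = np.array(DEFAULT_STANDARDS_G_L)
    intens = (scenario.fluor_intercept + scenario.fluor_slope * conc
              + scenario.fluor_noise_sd * rng.standard_normal(conc.size))
    standards = pd.DataFrame({"concentration_g_L": conc,
                              "intensity": intens})

    c_before = scenario.stock_g_l
    c_after = scenario.stock_g_l * (1 - true_capture_fraction)
    before = (scenario.fluor_intercept + scenario.fluor_slope * c_before
              + scenario.fluor_noise_sd
              * rng.standard_normal(n_replicates))
    after = (scenario.fluor_intercept + scenario.fluor_slope * c_after
             + scenario.fluor_noise_sd
             * rng.standard_normal(n_replicates))
    readings = pd.DataFrame({
        "replicate": np.arange(1, n_replicates + 1),
        "intensity_before": before,
        "intensity_after": after,
    })
    truth = {
        "capture_fraction": true_capture_fraction,
        "delta_c_g_L": c_before - c_after,
        "captured_mass_ng": (c_before - c_after) * scenario.volume_ml * 1e6,
        "volume_ml": scenario.volume_ml,
        "seed": scenario.seed,
    }
    return standards, readings, truth
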