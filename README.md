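# rsacap

Quantitative analysis of nano- and microplastic particle capture by thin
films (nanocellulose and related substrates), built around random
sequential adsorption (RSA) theory.

The package is for colloid/interface scientists who measure particle
adsorption with a quartz crystal microbalance with dissipation monitoring
(QCM-D), count the adsorbed particles in scanning electron micrographs, and
want to turn those raw signals into physically interpretable quantities:
adsorption rate coefficients, occupied area per particle, surface coverage
relative to the theoretical maximum, the amount of acoustically coupled
water, and particle-capture budgets from fluorescence depletion.

## The model

Equal spherical particles adsorbing irreversibly on a flat surface behave
as hard disks placed sequentially at random: once the surface coverage θ
reaches the jamming limit θ∞ ≈ 0.547 no further particle fits. The
adsorption kinetics for the surface mass density Γ (ng cm⁻²) are

    dΓ/dt = kₐ c B(Γ a / m),      Γ(0) = 0,

with adsorption rate coefficient kₐ (cm s⁻¹), bulk mass concentration c
(ng cm⁻³), occupied area per particle a and single-particle mass m. The
blocking function B(θ) — the probability that a random insertion attempt
succeeds — is the third-order expansion

    B(θ) = 1 − 4θ + (6√3/π) θ² + (40/(π√3) − 176/(3π²)) θ³   (θ < 0.3)

and near jamming the asymptote B(θ) = K₀ (θ∞ − θ)³ with K₀ ≈ 8.98. The
default "blended" kinetic regime switches between the two at their
intersection so the rate stays continuous.

QCM-D frequency shifts convert to areal mass through the Sauerbrey
relation Δm = −(C/n)Δf (C = 17.7 ng cm⁻² Hz⁻¹, overtone n). Because the
acoustic mass includes hydration water, traces are rescaled to the dry
mass obtained by particle counting in SEM images; the ratio of measured to
dry-mass-implied frequency shift is the coupled-water factor.

The package contains:

- `rsacap.rsa_model` — blocking functions, packing geometry, kinetic ODE;
- `rsacap.rsa_simulator` — Monte Carlo hard-disk deposition and jamming
  extrapolation (the independent check of θ∞);
- `rsacap.qcmd` — Sauerbrey conversion, dry-mass rescaling, coupled water,
  coverage summaries;
- `rsacap.fitting` — `RSAAdsorptionModel.fit()` →
  `RSAAdsorptionResults` (trust-region least squares over kₐ·c and a/m);
- `rsacap.sem` — histogram thresholding, single/cluster classification,
  particle densities;
- `rsacap.fluorescence` — calibration curves and depletion quantification;
- `rsacap.synthetic` — instrument emulators with ground truth.

## Worked example

Generate a hydrated QCM-D trace with known kinetics, rescale it to dry
mass and fit the RSA model:

```python
import rsacap as rc

scenario = rc.default_scenario(seed=1)          # kₐ=1e-5 cm/s, a=6e4 nm²
trace, truth = rc.generate_qcmd_trace(scenario)

hydrated = rc.sauerbrey_mass(trace.delta_f(5), 5,
                             normalization=trace.normalization)
gamma_dry_max = truth["gamma_dry"].max()
gamma_t = rc.rescale_to_dry_mass(hydrated, gamma_dry_max)

model = rc.RSAAdsorptionModel(trace.time, gamma_t,
                              concentration=1.0e5,   # 0.1 g/L in ng/cm³
                              particle_mass=5.26e-7)  # ng
res = model.fit()
print(res.summary())

water, rounded = rc.coupled_water_factor(trace.endpoint_delta_f(5),
                                         gamma_dry_max, n=5)
print(f"coupled-water factor: {water:.2f} (reported {rounded})")
```

Output:

```
RSA adsorption kinetics fit
==============================================
observations              2101
regime                 blended
adjusted R^2            0.9934
function evals              18
----------------------------------------------
              estimate     std err
k_a*c           0.9585      0.0036   ng/cm^2/s
a/m           0.001203     1.2e-06   cm^2/ng
k_a          9.585e-06     3.6e-08   cm/s
a            6.328e+04          61   nm^2
----------------------------------------------
coupled-water factor: 3.20 (reported 3.2)
```

The fit recovers the generating parameters (kₐ = 1.0 × 10⁻⁵ cm s⁻¹,
a = 6.0 × 10⁴ nm²) to within a few percent despite 2% multiplicative
noise, and the hydration factor of 3.2 means the acoustically sensed layer
weighs 3.2× its dry particle mass — over two thirds of the sensed mass is
coupled water.

A command-line interface wraps the same pipeline:

```sh
rsacap synth --seed 1 --out data/          # synthetic dataset
rsacap fit --qcmd data/qcmd.csv --images data/sem_0.tiff \
    --normalization raw --nm-per-px 2.0 --out results/
rsacap simulate --seeds 10 --out results/  # jamming-limit report
```

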