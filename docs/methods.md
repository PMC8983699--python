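# Methods

## Adsorption model

Particle adsorption on the film is treated as random sequential adsorption
(RSA) of equal hard disks: particles arrive at a constant rate, stick
irreversibly where they land (desorption coefficient fixed at zero — the
process is experimentally irreversible), never stack, and interact only by
steric exclusion. Under these assumptions the surface mass density
Γ (ng cm⁻²) obeys

    dΓ/dt = kₐ c B(θ),    θ = Γ a / m,

where kₐ (cm s⁻¹) is the adsorption rate coefficient, c (ng cm⁻³) the bulk
mass concentration, a the area occupied per adsorbed particle (including
strongly coupled water) and m the single-particle mass. The blocking
function B(θ) is the probability that a random insertion attempt is
accepted. Two closed forms are used:

- the third-order virial expansion
  `B(θ) = 1 − 4θ + (6√3/π)θ² + (40/(π√3) − 176/(3π²))θ³`,
  quantitatively valid for θ < 0.3 (it retains a residue of ≈ 0.032 at the
  jamming coverage and dips slightly negative near θ ≈ 0.47, so it is
  rejected outside [0, θ∞]);
- the near-jamming asymptote `B(θ) = K₀(θ∞ − θ)³` with θ∞ = 0.547 and
  K₀ = 8.98, exact at the fixed point.

The default integration regime ("blended") uses the expansion below and
the asymptote above their intersection θₓ ≈ 0.316, located once per
parameter set by bracketing and Brent's method (tolerance 1e−10); this
keeps the right-hand side continuous. The pure regimes remain selectable
because the two forms are also used separately in practice (the expansion
for fitting, the asymptote for saturation estimates at θ > 0.3).

Integration uses scipy's LSODA with rtol 1e−8 and atol 1e−10 ng cm⁻²; the
equation is smooth but flattens algebraically (~t^−1/2) near jamming.
Internal units are ng, cm, s, Hz throughout; areas quoted in nm² are
converted at the interface (1 nm² = 1e−14 cm²).

### Parameter estimation

`RSAAdsorptionModel.fit()` performs trust-region-reflective least squares
on the two composite coefficients kₐ·c (initial rate) and a/m (coverage
conversion), starting both at 0.1 with bounds [0, 10] in the internal unit
system, and integrating the ODE at every objective evaluation (fitting the
cumulative curve avoids differentiating noisy data). The composites
de-composite into kₐ and a given c and m. Because traces that saturate
early have a nearly flat likelihood in kₐ·c, the fitter by default adds
log-spaced multistarts around the nominal start and keeps the lowest-cost
converged solution; single-start fits reproduce the classical procedure.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹. Loss is
plain least squares (no robust weighting is assumed for instrument
noise); soft-L1 is available but off by default. The objective uses the
data's own timestamps without resampling. The fitted bounds are
unit-system specific: rescaling time units requires rescaling the bound
and the concentration consistently.

## Monte Carlo deposition

The simulator inserts disks of fixed diameter at uniformly random
positions, accepting an attempt iff it overlaps no accepted disk. Overlap
tests use a uniform grid hash with cell edge ≥ one diameter, so each test
inspects a 3×3 neighbourhood and runs in O(1); this is what makes
near-jamming runs affordable. Periodic boundaries are the default for
jamming estimation. Non-periodic boxes restrict centres to at least one
radius from the walls (minus-sampling of positions), so the reported
coverage — total disk area over box area without wall clipping — is an
unbiased bulk coverage.

Time is measured dimensionlessly as τ = attempts × disk area / box area.
Late-time coverage follows Feder's law θ(τ) = θ∞ − b·τ^(−1/2); the
jamming estimate is the intercept of a linear least-squares fit in
τ^(−1/2) over the window τ ≥ 50. With a 50-diameter periodic box and
τ = 220 per run, ten runs pool to θ∞ within ±0.003 of 0.547 in about half
a minute; these sizes are the package defaults for the jamming report.
The simulator also records the attempt index of every acceptance, from
which the empirical acceptance rate versus coverage is computed and
compared against B(θ) — the mean-field cross-check tying the simulator to
the closed-form kinetics.

## QCM-D processing

Frequency shifts convert to areal mass via the Sauerbrey relation
Δm = −(C/n)Δf with C = 17.7 ng cm⁻² Hz⁻¹ for a 5 MHz AT-cut crystal.
Instrument exports may report Δf raw or divided by the overtone number;
the convention is a mandatory declaration (`raw` / `normalized_by_n`) and
is never guessed — this is the single most error-prone ambiguity in the
workflow. All analysis is pinned to the fifth overtone; other overtones
are retained for quality control only. The Sauerbrey relation requires
dissipation shifts below 1e−5; particle layers typically violate this
(soft, water-laden films), which is exactly why the acoustic mass is
interpreted as hydrated mass and rescaled.

Rescaling multiplies the whole mass series by Γ_max(IA)/max m(t), pinning
the endpoint to the dry surface mass density from image analysis. The
coupled-water factor is Δf(QCM)/Δf(IA), where Δf(IA) = −Γ_IA·n/C is the
shift the dry mass alone would produce; it is reported unrounded and at
one decimal. Endpoints are read as the mean of the final 60 s after the
rinse rather than the global extremum, for robustness against spikes.

Coverage summaries report: dry (solid/air) coverage θ = (Γ_IA/m)·π(d_eff/2)²
with the effective diameter d_eff = 1.1·d_abs (electrical double layer
plus hydration shell); hydrated (solid/liquid) coverage Γ·a/m with the
fitted a; the circular-equivalent diameter d_RSA = 2√(a/π); and the
fractional coverage θ/θ∞. Presentation rounding (coverages and d_RSA to
2 significant figures, water factor to 1 decimal) applies only in the
human-readable table.

Two single-particle masses coexist deliberately: 5.49 × 10⁻⁷ ng for a
100 nm polystyrene sphere at the supplier density 1.05 g cm⁻³ (used in
fluorescence counting) and 5.26 × 10⁻⁷ ng as the image-analysis
convention (implying ρ ≈ 1.005 g cm⁻³); each module defaults to the value
conventional for its measurement and both are explicit parameters.

## SEM particle counting

Segmentation is a global threshold on the 256-bin histogram: the histogram
is smoothed (moving average, 5 bins), the most prominent peak at or below
the median gray level is taken as the background, and the threshold is
placed on its descending side — at the first level whose smoothed count
falls below a fraction f = 0.01 of the peak, or, when bright and edge
pixels keep the histogram above that cutoff everywhere (dense or clustered
fields), at the first level where the flank has flattened (count below 20%
of the peak and no longer decreasing). Both f and the smoothing window are
configuration keys; the peak-side placement is the stated strategy, the
numeric cutoffs are this package's operational choices.

Connected components are classified against the nominal single-particle
footprint A₁ = π(d/2)² (d known per image from the scale-bar calibration):
singles are components with area in [0.5, 1.5]·A₁ and circularity
4πA/P² ≥ 0.75; sub-half-particle components are noise. In `detached` mode,
components of 1.5–4.5·A₁ are assumed to be three touching particles — the
small-cluster convention — and larger blobs decompose by area. In
`clustered` mode every non-single component contributes round(area/A_unit)
particles. A_unit defaults to the median measured single area when at
least five singles are present (self-calibration): thresholding dilates
every object by the same point-spread halo, and dividing by the nominal
A₁ would overcount clusters by ~10% at typical magnifications. The
nominal behaviour is available with `self_calibrate=False`. An `auto`
mode selects `clustered` when most foreground area lies outside singles.
Edge objects are included (plus-sampling); with monodisperse particles
this introduces no size-dependent sampling bias. A final sanity check
rejects densities whose implied coverage exceeds the hexagonal packing
bound π/(2√3).

Counts convert to particles mm⁻² and, with m, to Γ = density·100·m
(ng cm⁻²). Multiple fields per sample are averaged by the caller (the CLI
averages all supplied images).

## Fluorescence depletion

Calibration is an ordinary least-squares line with intercept over the
standard series {0, 0.025, 0.05, 0.075, 0.1} g L⁻¹ (the blank is a
standard, hence the free intercept). Captured mass is Δc·V; the particle
count divides by the sphere mass of the specified particle and is only
offered for monodisperse particles — heterogeneous particles (e.g.
polydisperse polyethylene) get mass-only reports. Triplicate scatter
propagates to the reported SD as V/m times the SD of Δc. Depletion
slightly negative within 3 SD is clipped to zero; beyond that it is an
error. The film area needed to capture an entire particle budget is
total/rate, rounded up to whole cm². The immersion volume is a required
input; it cannot be inferred from intensities.

## Synthetic data

The generators emulate the reference experimental conditions: a 0.1 g L⁻¹
(1e5 ng cm⁻³) particle dispersion adsorbing for 1 h, kinetics kₐ = 1e-5
cm s⁻¹ and a = 6e4 nm² (a nanocellulose-like system), hydration factor
3.2, 2% multiplicative QCM-D noise (frequency noise scales with load), a
10-minute noiseless rinse plateau, SEM-like frames with Gaussian
background (mean 30, σ 8 on the 8-bit scale) and anti-aliased bright disks
blurred by σ = 1 px, and linear fluorescence responses with additive
noise. Every generator is a pure function of (scenario, seed) and emits
its ground truth.

What the generators do *not* emulate — and hence what passing recovery
tests do not show about real data: transport limitation in the flow cell
(the arrival rate is taken as constant), viscoelastic dissipation physics
(the ΔD channel is a proportional placeholder scaled into the 5–50 × 10⁻⁶
band and carries no Voigt-model content), temperature drift, SEM charging
and astigmatism artefacts, polydispersity, and real cluster morphology
beyond touching triplets. Forward integration of the default scenario
gives a dry endpoint of ≈ 379 ng cm⁻² after 1 h (the kinetics are still
≈ 10% short of the plateau-like values a longer run would reach).

Image placement uses the hard-disk simulator with the exclusion diameter
inflated by 1.15 so rendered singles cannot touch at tangency and merge
after blurring; injected clusters are equilateral touching triplets.
Coverage targets are capped at 0.5 — approaching jamming makes rejection
sampling astronomically slow and exceeds anything observed on real films.

## Problem sizes and tolerances

Defaults were chosen so every standard analysis runs in seconds to tens of
seconds on one CPU: jamming estimation uses ten 50-diameter periodic boxes
at τ = 220 (pooled estimate within ±0.01 of 0.547 with large margin);
recovery simulations use 20 seeds at 1-hour traces sampled every 10–20 s;
image tests use 1024 × 768 frames at 4 nm px⁻¹ (the instrument-class
2048 × 1536 geometry is the generator default for production use).
Parameter recovery at 2% noise is better than 5% median error for kₐ and
a across the physical range kₐ ∈ [0.5, 5]×10⁻⁵ cm s⁻¹,
a ∈ [1, 24]×10⁴ nm²; planted-count recovery is within 5% at coverage
≤ 0.1 (detached fields) and within 10% at coverage 0.3 (clustered
fields).

## Known limitations

- The RSA model assumes monodisperse disks; polydisperse systems jam at
  higher coverage and are out of scope.
- The blocking-expansion/asymptote blend is a continuous approximation,
  not the exact B(θ); between θ = 0.3 and jamming the true function is
  known only numerically.
- Sauerbrey conversion on high-dissipation layers yields hydrated mass by
  construction; no viscoelastic inversion is attempted.
- The image analyser does not split touching particles by watershed; the
  cluster conventions (3-particle assumption, area division) inherit the
  counting bias of those conventions.
- Fit standard errors are asymptotic Gauss–Newton values and ignore
  serial correlation of instrument noise.
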