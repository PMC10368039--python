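# Methods

`cartopt` estimates the absorption coefficient μa(λ) and reduced scattering
coefficient μs′(λ) of articular cartilage over 400–1400 nm from calibrated
integrating-sphere measurements of diffuse reflectance R(λ) and total
transmittance T(λ), and quantifies how sensitive those estimates are to the
parameters of the measurement setup and the inversion. This note documents
the models, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Forward model: Monte Carlo photon transport

The sample construct is a cylinder of cartilage (default radius 7 mm,
thickness 0.5–3 mm) held between two clear glass windows (n = 1.52,
1 mm thick) inside a cylindrical holder (radius 9 mm). The lateral gap
between sample and holder wall is filled with air (n = 1.0) or water
(n = 1.33, absorption taken from the water component spectrum); the holder
wall is treated as perfectly absorbing, so weight reaching it is tallied as
side loss. A collimated top-hat beam (default radius 1 mm) enters the top
window at normal incidence; z increases downward and all lengths are mm.

Photon packets are transported with the standard weighted scheme:

- free paths are exponential with attenuation μt = μa + μs;
- at each interaction the fraction μa/μt of the packet weight is deposited
  (implicit capture) and the direction is deflected by the
  Henyey–Greenstein phase function
  p(θ; g) = (1/4π)(1 − g²)/(1 + g² − 2g cos θ)^{3/2},
  sampled through its closed-form inverse CDF, with uniform azimuth (the
  phase function is azimuthally symmetric);
- every dielectric interface (window/sample, window/gap, sample/gap lateral
  cylinder, window/ambient) applies unpolarized Fresnel
  reflection/refraction probabilistically;
- packets below weight 1e-4 undergo Russian roulette with survival
  probability 0.1.

Weight escaping through the top window is tallied as diffuse reflectance if
the packet ever scattered, otherwise as the specular return of the
unscattered beam (excluded from R, as sphere measurements exclude it
through the port geometry); all weight escaping through the bottom is total
transmittance. Collection is ideal: every top-escaping diffuse packet
counts, with no port aperture.

Bookkeeping is exact: the tallies (specular R, diffuse R, total T, sample
absorption, gap absorption, side loss) plus the realized Russian-roulette
imbalance sum to 1 to float precision (< 1e-9 per run, enforced by test).
The random stream is an explicit xorshift64* generator seeded through
splitmix64, so identical inputs and seed give bit-identical tallies — the
basis of every common-random-number comparison below.

Refractive index of cartilage defaults to n = 1.358; the anisotropy factor
is treated as wavelength-independent within a run and swept over
{0.8, 0.9, 0.99} across runs, since its spectral behaviour in cartilage is
not established.

### Sample-volume irregularity

Detaching cartilage from bone leaves an irregular bottom face. This is
modelled geometrically, not as bookkeeping: a relative volume deficit u
truncates the cylinder's bottom with an oblique plane of depth
u·thickness at maximal tilt (slope = depth/radius), and the pocket fills
with the gap medium. The cohort generator draws u uniformly on
[0, 0.18] by default, matching the observed deviation of real samples from
a perfect cylinder (less than ~18%).

### Bottom-surface roughness

Maximal roughness of the bottom face is modelled as a Lambertian interface:
the reflect/transmit split still uses the Fresnel coefficient at the
packet's actual incidence, but the outgoing direction (on either side) is
redrawn cosine-weighted about the surface normal, i.e. photons leave the
interface "in all directions" instead of specularly. This is a nominal
maximal-roughness model; microfacet slopes and shadowing are not modelled.

## Inverse model: lookup-table inversion

A lookup table stores simulated R and T surfaces over a strictly increasing
(μa, μs′) grid for fixed geometry, g and n, with μs = μs′/(1 − g) at each
node and one shared seed across nodes. Estimation minimizes

  ((R(μa, μs′) − R_meas)/σ_R)² + ((T(μa, μs′) − T_meas)/σ_T)²

over bicubic splines of the surfaces on log-parameter axes, starting
Nelder–Mead from the best grid node (ties break toward smaller μa, the
stable choice in the low-absorption regime). σ_R, σ_T are the Monte Carlo
standard errors of the table build, floored at 1e-4. Estimates touching the
grid hull are flagged `on_boundary`; delta-method standard errors come from
the local surface Jacobian. The production default grid is μa log-spaced on
[1e-4, 5] mm⁻¹ and μs′ on [0.05, 10] mm⁻¹ (20 nodes each), spanning the
literature range for cartilage; the sensitivity experiments use a locally
refined grid around the cartilage-like truth (μa on [1e-4, 0.5], 14 nodes;
μs′ on [0.3, 3], 10 nodes).

The full sphere-throughput/detector model of the physical instrument is out
of scope; synthetic data provides calibrated R/T directly, and a simplified
substitution calibration (ρ_ref · raw/raw_ref, clipped to [0, ρ_ref]) is
available for raw-count workflows.

`SpectralInversion` wraps the per-wavelength inversion in a model/results
interface: the model holds a measurement record and the forward table(s);
`fit()` returns results carrying both property spectra, their standard
errors, residuals, boundary flags, the QC decision and a `summary()` table.

## Theoretical absorption reference and QC

Cartilage μa is compared against a volume-fraction mixture of its
constituents, μa,th = Σ_c V_c μa,c, with default fractions water 0.68,
collagen 0.30, elastin 0.01, lipid 0.01. The bundled component spectra are
synthetic stand-ins generated in code (no downloads): a water-like curve
with absorption bands near 970, 1200 and 1440 nm rising to ~1 mm⁻¹,
monotone power-law collagen and elastin, and a weak monotone lipid; real
literature spectra can be supplied as delimited text instead.

Estimated μa spectra are removed when they show signal distortion:
any value ≤ 1e-5 mm⁻¹ (`below_floor`); coefficient of variation over the
band < 0.05 (`flat_signal`, an operationalization of "signal flattening");
or Pearson correlation with μa,th over 900–1400 nm < 0.5
(`missing_features` — the exact published criteria are not available, so
these thresholds are declared defaults, all configurable).

## Sensitivity analyses

Relative differences are always 100·(test − reference)/reference with the
reference being the second arm (theoretical μa, the g = 0.9 arm, the smooth
arm, or the n = 1.358 arm), so underestimation is negative. Cohort curves
are summarized by pointwise medians and 1st/3rd quartiles
(linear-interpolation quantile definition).

- **Anisotropy factor.** A record forward-simulated at the true g = 0.9 is
  inverted with tables built at g = 0.8, 0.9, 0.99 (one seed for all
  tables). By the similarity relation, R and T at fixed μs′ are nearly
  invariant for g ≳ 0.8, so recovered properties should barely move.
- **Refractive index.** The same record is inverted with tables built at
  n = 1.3, 1.358, 1.5.
- **Roughness.** A 2 mm slab is simulated smooth and fully Lambertian
  (common random numbers) and both arms are inverted against the smooth
  table.
- **Surrounding medium.** Records are inverted with air-gap and water-gap
  tables and each recovered μa is compared against μa,th.
- **Volume irregularity.** Per-sample volume deviations are correlated with
  μa deviations; both variables pass through a normality check
  (Shapiro–Wilk at α = 0.05 — a dedicated normality test; a t-test cannot
  assess normality) that gates Pearson vs Spearman correlation.

### Experiment problem sizes

The sensitivity experiments run on a cartilage-like truth: mixture μa with
default fractions, μs′ = 1.5·(λ/500)^{−1} mm⁻¹, g = 0.9, n = 1.358, 2 mm
slab, air gap, 21 wavelengths evenly spaced over 500–1300 nm (the roughness
study uses a flat μs′ = 1.5 mm⁻¹). Defaults are 50 000 photons per record
wavelength and 50 000 per table node (the g and n arms share one seed), a
budget at which the ~1% systematic anisotropy effect stands above the
table's Monte Carlo noise; a full sweep runs in minutes on one CPU and all
sizes are keyword arguments. The round-trip recovery experiment draws 50
(μa, μs′) pairs log-uniformly inside a 16×16-node table on
μa ∈ [5e-3, 1] × μs′ ∈ [0.3, 5] mm⁻¹, forward-simulates each at 10⁵
photons and inverts them.

## Synthetic cohorts

The generator emulates the statistical structure of per-site cohorts
(femoral, patellar, tibial × lateral/medial): volume fractions jittered
(σ = 0.02, renormalized), power-law scattering with amplitude
1.0–2.5 mm⁻¹ and exponent 0.5–1.5, thickness uniform on 0.5–3 mm, diameter
14 mm, volume deficit up to 18%, and independent multiplicative log-normal
noise on R and T with CV 0.01. All randomness descends from one root seed
via `SeedSequence` spawning. The default wavelength grid is 50 nm steps
over 400–1400 nm (21 points), a desk-scale choice; the instrument's 3–7 nm
resolution is a config option.

What the synthetic cohorts do not emulate: the physical sphere throughput
and detector chain (measurements are ideal-collection tallies plus noise),
chromatic refractive indices, real chromophore line shapes, spatial
heterogeneity within a sample, and freeze–thaw or preparation artifacts.
Passing round-trip tests therefore demonstrates the self-consistency and
noise robustness of the estimation pipeline, not the accuracy of the
physical instrument model.

## Numerical choices and degenerate inputs

- Interaction-free media propagate packets straight to the next boundary;
  boundary positions are nudged 1e-9 mm along the direction of travel to
  avoid re-intersecting the surface just left.
- Free-path resampling after a boundary crossing is exact (exponential
  memorylessness).
- Spline degree falls back from bicubic when a grid axis has fewer than 4
  nodes; grids containing zero switch that axis from log to linear.
- `invert_rt` warns but proceeds when R + T > 1; (0, 0) inputs resolve on
  the grid hull with `on_boundary` set.
- The quantile definition is linear interpolation between order statistics
  throughout.
- Empty spectra invert to empty spectra without error.

## Known limitations

- Ideal collection and a perfectly absorbing holder wall make side loss,
  and therefore the refractive-index sensitivity of the recovered μa,
  larger than a calibrated sphere measurement would show; the
  refractive-index experiment should be read as an upper bound for this
  construct.
- The anisotropy factor is wavelength-independent within a run.
- Polarization, time-resolved transport, sphere-port ray tracing, modified
  Henyey–Greenstein and Mie/Rayleigh phase-function mixtures are out of
  scope.
- The component library is a stand-in; absolute μa levels are only as
  realistic as its magnitudes.
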