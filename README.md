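# cartopt

Inverse Monte Carlo estimation of articular-cartilage optical properties —
the absorption coefficient μa(λ) and the reduced scattering coefficient
μs′(λ) over 400–1400 nm — from integrating-sphere measurements of diffuse
reflectance R(λ) and total transmittance T(λ), together with the
sensitivity analyses that quantify how fragile those estimates are to the
measurement setup.

It is written for researchers in biomedical optics and cartilage biomechanics
who need wavelength-resolved tissue optical properties from sphere
measurements, and who need to know how much of the spread in published
cartilage values is biology versus apparatus.

## The method

A cylindrical cartilage sample (≈14 mm diameter, 0.5–3 mm thick) sits
between glass windows in a holder whose lateral gap holds air or water.
Estimation is a two-step procedure:

1. **Forward model.** Weighted-photon Monte Carlo transport through the
   full construct: exponential free paths with μt = μa + μs, implicit
   capture, Henyey–Greenstein scattering

   p(θ; g) = (1/4π) (1 − g²) / (1 + g² − 2g cos θ)^{3/2},

   unpolarized Fresnel events at every dielectric interface, Russian
   roulette termination, and exact weight bookkeeping (all tallies sum to 1
   to < 1e-9 per run). R and T surfaces are precomputed on a (μa, μs′)
   lookup grid with common random numbers, with μs = μs′/(1 − g) and
   n = 1.358 by default.

2. **Inversion.** Each measured (R, T) pair is matched to the surfaces by
   minimizing ((R̂ − R)/σ_R)² + ((T̂ − T)/σ_T)² over bicubic spline
   interpolants on log-parameter axes (Nelder–Mead from the best node).

A chromophore mixture μa,th = Σ_c V_c μa,c (water 0.68, collagen 0.30,
elastin 0.01, lipid 0.01) provides the theoretical absorption reference
used for QC: estimated μa spectra that are implausibly low (≤ 1e-5 mm⁻¹),
flat, or uncorrelated with the reference's near-infrared features are
flagged for removal.

Sensitivity experiments re-invert forward-simulated records under perturbed
assumptions — anisotropy factor g ∈ {0.8, 0.9, 0.99}, refractive index
1.3–1.5, air vs water in the lateral gap, a fully Lambertian (maximally
rough) bottom face, and cylinder-volume irregularity — and report relative
differences in percent against the baseline arm. See `docs/methods.md` for
the models and all numerical choices.

## Worked example

Estimate properties of a synthetic sample from its simulated R/T record:

```python
import numpy as np
from cartopt import SampleConstruct, build_lut, SpectralInversion
from cartopt.synthetic import SyntheticCohortConfig, generate_cohort

config = SyntheticCohortConfig(
    sites=("FL",), n_per_site=1, noise_cv=0.01,
    thickness_range_mm=(2.0, 2.0), volume_irregularity_max=0.0,
    wavelengths_nm=tuple(np.arange(500.0, 1301.0, 100.0)), seed=42,
)
sample = generate_cohort(config, n_photons=20_000)[0]

lut = build_lut(
    np.geomspace(3e-3, 0.3, 10), np.geomspace(0.4, 3.0, 8),
    sample.construct, g=0.9, n_sample=1.358, n_photons=20_000, seed=7,
)
results = SpectralInversion(sample.record, lut).fit()
print(results.summary())
```

prints (abridged):

```
Spectral inversion of integrating-sphere R/T
====================================================
sample id      : FL01   site: FL
wavelengths    : 9 points [500, 1300] nm
on-boundary    : 0 / 9
median residual: 9.99e-15
----------------------------------------------------
 wavelength_nm     mu_a    se_mu_a  mu_s_prime  se_mu_s_prime  on_boundary
           500 0.027473  0.0010079      2.1912       0.023745        False
           600 0.022569 0.00092083      1.7718       0.020273        False
           700 0.018229 0.00090923      1.4844       0.020882        False
           ...
          1200 0.074408  0.0014692     0.68368      0.0079568        False
          1300 0.057017  0.0013294     0.60538      0.0069006        False
```

The estimated μa (mm⁻¹) tracks the water bands of the mixture reference
(the rises at 1000 and 1200 nm) and μs′ (mm⁻¹) falls with wavelength as the
generator's power law prescribes; each estimate carries a delta-method
standard error from the lookup-table Monte Carlo noise. The true values for
this sample are μa(500) = 0.0275 mm⁻¹ and μs′(500) = 2.215 mm⁻¹ — the fit
recovers both to about a percent.

A command-line pipeline covers the same stages
(`cartopt synth | build-lut | invert | qc | sensitivity | report`).

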