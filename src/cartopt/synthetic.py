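"""Synthetic cartilage cohorts with the statistical structure the analysis
assumes.

Each sample is a cylinder (diameter ~14 mm, thickness 0.5-3 mm) whose true
absorption spectrum is a chromophore mixture with jittered volume fractions,
whose reduced scattering follows a power law in wavelength, and whose bottom
face may be obliquely truncated to emulate the irregular cartilage-bone
interface.  Measurements are forward Monte Carlo R/T tallies with
multiplicative log-normal noise.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so cohorts are reproducible and per-sample streams independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mixture import DEFAULT_FRACTIONS, default_component_library, mixture_absorption
from .montecarlo import AIR, WATER, GapMedium, SampleConstruct, simulate_rt
from .records import MeasurementRecord
from .spectra import OpticalProperties, Spectrum

__all__ = [
    "SITES",
    "SyntheticCohortConfig",
    "SyntheticSample",
    "generate_true_spectra",
    "generate_geometry",
    "simulate_measurement",
    "generate_cohort",
    "cohort_manifest",
]

#: Anatomical sites: femoral/patellar/tibial, lateral/medial.
SITES = ("FL", "FM", "PL", "PM", "TL", "TM")

SCATTER_REF_NM = 500.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort."""

    sites: tuple = SITES
    n_per_site: int = 3
    thickness_range_mm: tuple = (0.5, 3.0)
    diameter_mm: float = 14.0
    volume_irregularity_max: float = 0.18
    fraction_jitter_sd: float = 0.02
    scatter_amplitude_range: tuple = (1.0, 2.5)  # mm^-1 at 500 nm
    scatter_power_range: tuple = (0.5, 1.5)
    noise_cv: float = 0.01
    g_true: float = 0.9
    n_true: float = 1.358
    gap: str = "air"  # or "water"
    wavelengths_nm: tuple = tuple(np.arange(400.0, 1401.0, 50.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_site < 1:
            raise ValueError("n_per_site must be >= 1")
        for name in ("thickness_range_mm", "scatter_amplitude_range", "scatter_power_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.volume_irregularity_max < 1.0:
            raise ValueError("volume_irregularity_max must lie in [0, 1)")
        if any(s not in SITES for s in self.sites):
            raise ValueError(f"sites must be drawn from {SITES}")
        if self.gap not in ("air", "water"):
            raise ValueError("gap must be 'air' or 'water'")

    def replace(self, **kw) -> "SyntheticCohortConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SyntheticSample:
    """One generated sample: ground truth plus (optionally) a measurement."""

    sample_id: str
    site: str
    mu_a: Spectrum
    mu_s_prime: Spectrum
    g: float
    n: float
    fractions: dict
    scatter_amplitude: float
    scatter_power: float
    construct: SampleConstruct
    record: MeasurementRecord | None = None

    @property
    def nominal_volume(self) -> float:
        return self.construct.nominal_volume

    @property
    def true_volume(self) -> float:
        return self.construct.true_volume

    def props_at(self, index: int) -> OpticalProperties:
        return OpticalProperties.from_reduced(
            float(self.mu_a.values[index]),
            float(self.mu_s_prime.values[index]),
            self.g,
            self.n,
        )


def _jitter_fractions(rng: np.random.Generator, sd: float) -> dict:
    base = np.array([DEFAULT_FRACTIONS[c] for c in DEFAULT_FRACTIONS])
    for _ in range(1000):
        jittered = base + rng.normal(0.0, sd, size=base.size)
        if np.all(jittered > 0):
            jittered /= jittered.sum()
            return dict(zip(DEFAULT_FRACTIONS, jittered))
    raise RuntimeError("fraction jitter failed to produce positive fractions")


def generate_true_spectra(config: SyntheticCohortConfig, rng: np.random.Generator):
    """Draw one sample's true property spectra.

    mu_a is the mixture reference with volume fractions jittered around
    (0.68, 0.30, 0.01, 0.01) and renormalized; mu_s' is a power law
    a * (lambda/500)^(-b).  Returns (mu_a, mu_s_prime, fractions, a, b).
    """
    wl = np.asarray(config.wavelengths_nm, dtype=float)
    fractions = (
        _jitter_fractions(rng, config.fraction_jitter_sd)
        if config.fraction_jitter_sd > 0
        else dict(DEFAULT_FRACTIONS)
    )
    lib = default_component_library(wl, fractions)
    mu_a = mixture_absorption(lib)
    a = rng.uniform(*config.scatter_amplitude_range)
    b = rng.uniform(*config.scatter_power_range)
    mu_s_prime = Spectrum(wl, a * (wl / SCATTER_REF_NM) ** (-b), "mm^-1")
    return mu_a, mu_s_prime, fractions, float(a), float(b)


def generate_geometry(config: SyntheticCohortConfig, rng: np.random.Generator) -> SampleConstruct:
    """Draw a sample construct: thickness uniform in range, volume deficit
    uniform in [0, volume_irregularity_max] realized as an oblique bottom cut."""
    thickness = rng.uniform(*config.thickness_range_mm)
    deficit = (
        rng.uniform(0.0, config.volume_irregularity_max)
        if config.volume_irregularity_max > 0
        else 0.0
    )
    gap = AIR if config.gap == "air" else WATER
    return SampleConstruct(
        sample_radius=config.diameter_mm / 2.0,
        sample_thickness=float(thickness),
        gap_medium=gap,
        cut_fraction=float(deficit),
    )


def _gap_at(construct: SampleConstruct, wavelength: float, water_mu_a: Spectrum | None) -> SampleConstruct:
    if construct.gap_medium.name != "water" or water_mu_a is None:
        return construct
    mu = float(np.interp(wavelength, water_mu_a.wavelengths, water_mu_a.values))
    return construct.with_(gap_medium=GapMedium("water", mu_a=mu, n=construct.gap_medium.n))


def simulate_measurement(
    sample: SyntheticSample,
    n_photons: int,
    rng: np.random.Generator,
    mc_seed: int | None = None,
    noise_cv: float = 0.0,
) -> MeasurementRecord:
    """Forward-simulate the sample's R/T record.

    One Monte Carlo seed is shared across wavelengths (common random
    numbers), then independent multiplicative log-normal noise with the
    given coefficient of variation is applied to R and T.
    """
    if mc_seed is None:
        mc_seed = int(rng.integers(0, 2**31 - 1))
    wl = sample.mu_a.wavelengths
    water_ref = None
    if sample.construct.gap_medium.name == "water":
        water_ref = default_component_library(wl).spectra["water"]
    R = np.empty(wl.size)
    T = np.empty(wl.size)
    for i, lam in enumerate(wl):
        res = simulate_rt(
            sample.props_at(i),
            _gap_at(sample.construct, float(lam), water_ref),
            n_photons,
            mc_seed,
        )
        R[i] = res.R_diffuse
        T[i] = res.T_total
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        R = R * np.exp(rng.normal(0.0, sigma, wl.size) - 0.5 * sigma**2)
        T = T * np.exp(rng.normal(0.0, sigma, wl.size) - 0.5 * sigma**2)
    return MeasurementRecord(
        wavelengths=wl,
        R=np.clip(R, 0.0, 1.0),
        T=np.clip(T, 0.0, 1.0),
        site=sample.site,
        sample_id=sample.sample_id,
        seed=mc_seed,
        metadata={"n_photons": n_photons, "noise_cv": noise_cv},
    )


def generate_cohort(
    config: SyntheticCohortConfig,
    n_photons: int = 20_000,
    with_measurements: bool = True,
) -> list[SyntheticSample]:
    """Generate the full cohort described by ``config``."""
    root = np.random.SeedSequence(config.seed)
    samples: list[SyntheticSample] = []
    streams = root.spawn(len(config.sites) * config.n_per_site)
    k = 0
    for site in config.sites:
        for j in range(config.n_per_site):
            rng = np.random.default_rng(streams[k])
            k += 1
            mu_a, mu_s_prime, fractions, a, b = generate_true_spectra(config, rng)
            construct = generate_geometry(config, rng)
            sample = SyntheticSample(
                sample_id=f"{site}{j + 1:02d}",
                site=site,
                mu_a=mu_a,
                mu_s_prime=mu_s_prime,
                g=config.g_true,
                n=config.n_true,
                fractions=fractions,
                scatter_amplitude=a,
                scatter_power=b,
                construct=construct,
            )
            if with_measurements:
                record = simulate_measurement(
                    sample, n_photons, rng, noise_cv=config.noise_cv
                )
                sample = replace(sample, record=record)
            samples.append(sample)
    return samples


def cohort_manifest(samples: list[SyntheticSample]) -> pd.DataFrame:
    """Delimited-text-ready manifest: one row per sample."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "site": s.site,
                "thickness_mm": s.construct.sample_thickness,
                "diameter_mm": 2 * s.construct.sample_radius,
                "nominal_volume_mm3": s.nominal_volume,
                "true_volume_mm3": s.true_volume,
                "scatter_amplitude": s.scatter_amplitude,
                "scatter_power": s.scatter_power,
                "g": s.g,
                "n": s.n,
                "gap": s.construct.gap_medium.name,
                "mc_seed": s.record.seed if s.record is not None else -1,
            }
        )
    return pd.DataFrame(rows)
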