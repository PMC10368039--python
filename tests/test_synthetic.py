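"""Synthetic cohort generation: truth spectra, geometry, noise model, and
end-to-end identifiability."""

import numpy as np
import pytest

from cartopt import build_lut
from cartopt.mixture import default_component_library, mixture_absorption
from cartopt.model import invert_spectrum
from cartopt.synthetic import (
    SITES,
    SyntheticCohortConfig,
    generate_cohort,
    generate_geometry,
    generate_true_spectra,
    simulate_measurement,
    cohort_manifest,
)

WAVELENGTHS = tuple(np.arange(500.0, 1301.0, 50.0))


class TestTrueSpectra:
    def test_zero_jitter_reproduces_mixture_and_power_law(self):
        config = SyntheticCohortConfig(
            fraction_jitter_sd=0.0,
            scatter_amplitude_range=(1.5, 1.5),
            scatter_power_range=(1.0, 1.0),
            wavelengths_nm=WAVELENGTHS,
        )
        rng = np.random.default_rng(0)
        mu_a, mu_s, fractions, a, b = generate_true_spectra(config, rng)
        wl = np.asarray(WAVELENGTHS)
        expected_mu_a = mixture_absorption(default_component_library(wl))
        assert np.allclose(mu_a.values, expected_mu_a.values)
        assert np.allclose(mu_s.values, 1.5 * (wl / 500.0) ** -1.0)
        assert fractions == pytest.approx(
            {"water": 0.68, "collagen": 0.30, "elastin": 0.01, "lipid": 0.01}
        )

    def test_jittered_fractions_renormalize(self):
        config = SyntheticCohortConfig(fraction_jitter_sd=0.05)
        rng = np.random.default_rng(1)
        sums = [
            sum(generate_true_spectra(config, rng)[2].values()) for _ in range(10_000)
        ]
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_default_optical_constants(self):
        config = SyntheticCohortConfig()
        assert config.n_true == 1.358
        assert config.g_true == 0.9
        assert config.diameter_mm == 14.0


class TestGeometry:
    def test_no_irregularity_gives_perfect_cylinder(self):
        config = SyntheticCohortConfig(volume_irregularity_max=0.0)
        construct = generate_geometry(config, np.random.default_rng(2))
        assert construct.true_volume == pytest.approx(
            np.pi * 7.0**2 * construct.sample_thickness
        )

    def test_volume_deficit_bounded_by_default_18_percent(self):
        config = SyntheticCohortConfig()
        rng = np.random.default_rng(3)
        for _ in range(10_000):
            c = generate_geometry(config, rng)
            deficit = (c.nominal_volume - c.true_volume) / c.nominal_volume
            assert 0.0 <= deficit <= 0.18

    def test_thickness_within_configured_range(self):
        config = SyntheticCohortConfig(thickness_range_mm=(0.5, 3.0))
        rng = np.random.default_rng(4)
        th = [generate_geometry(config, rng).sample_thickness for _ in range(200)]
        assert min(th) >= 0.5 and max(th) <= 3.0


class TestMeasurement:
    def test_deterministic_for_same_config(self):
        config = SyntheticCohortConfig(
            sites=("FL",), n_per_site=1, wavelengths_nm=WAVELENGTHS[:3], seed=5
        )
        a = generate_cohort(config, n_photons=2000)[0]
        b = generate_cohort(config, n_photons=2000)[0]
        assert np.array_equal(a.record.R, b.record.R)
        assert np.array_equal(a.record.T, b.record.T)

    def test_zero_noise_equals_forward_tallies(self):
        config = SyntheticCohortConfig(
            sites=("FL",), n_per_site=1, noise_cv=0.0,
            wavelengths_nm=WAVELENGTHS[:3], seed=6,
        )
        sample = generate_cohort(config, n_photons=2000)[0]
        redo = simulate_measurement(
            sample, 2000, np.random.default_rng(0), mc_seed=sample.record.seed
        )
        assert np.array_equal(sample.record.R, redo.R)

    def test_noise_cv_calibration(self):
        """Multiplicative noise reproduces the configured CV."""
        rng = np.random.default_rng(7)
        cv = 0.02
        sigma = np.sqrt(np.log1p(cv**2))
        base = 0.4
        draws = base * np.exp(rng.normal(0.0, sigma, 200) - 0.5 * sigma**2)
        measured_cv = draws.std(ddof=1) / draws.mean()
        assert 0.015 < measured_cv < 0.025

    def test_site_labels_do_not_influence_generation(self):
        kw = dict(n_per_site=1, wavelengths_nm=WAVELENGTHS[:3], seed=8)
        a = generate_cohort(SyntheticCohortConfig(sites=("FL", "TM"), **kw), 1000)
        b = generate_cohort(SyntheticCohortConfig(sites=("PM", "FM"), **kw), 1000)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.record.R, s2.record.R)
            assert s1.construct.sample_thickness == s2.construct.sample_thickness


class TestManifest:
    def test_manifest_columns_and_rows(self):
        config = SyntheticCohortConfig(
            sites=SITES[:2], n_per_site=2, wavelengths_nm=WAVELENGTHS[:3], seed=9
        )
        samples = generate_cohort(config, n_photons=500)
        manifest = cohort_manifest(samples)
        assert len(manifest) == 4
        assert {"sample_id", "site", "thickness_mm", "true_volume_mm3"} <= set(
            manifest.columns
        )


class TestIdentifiability:
    def test_cohort_round_trip_recovers_truth(self):
        """Low-noise cohort inverted with matched-geometry tables recovers
        mu_s' (median rel. error < 5%) and mu_a (< 15%) over 500-1300 nm."""
        config = SyntheticCohortConfig(
            sites=("FL",),
            n_per_site=2,
            noise_cv=0.01,
            thickness_range_mm=(1.5, 2.5),
            wavelengths_nm=WAVELENGTHS,
            seed=10,
        )
        samples = generate_cohort(config, n_photons=30_000)
        err_a, err_s = [], []
        for sample in samples:
            lut = build_lut(
                np.geomspace(3e-3, 0.3, 10),
                np.geomspace(0.4, 3.0, 8),
                sample.construct,
                g=sample.g,
                n_sample=sample.n,
                n_photons=20_000,
                seed=101,
            )
            mu_a_hat, mu_s_hat, _ = invert_spectrum(sample.record, lut)
            err_a.extend(
                np.abs(mu_a_hat.values - sample.mu_a.values) / sample.mu_a.values
            )
            err_s.extend(
                np.abs(mu_s_hat.values - sample.mu_s_prime.values)
                / sample.mu_s_prime.values
            )
        assert np.median(err_s) < 0.05
        assert np.median(err_a) < 0.15
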