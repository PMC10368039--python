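"""Monte Carlo forward model: analytic limits, conservation, monotonicity."""

import math

import numpy as np
import pytest

from cartopt import OpticalProperties, SampleConstruct, simulate_rt
from cartopt.montecarlo import (
    GapMedium,
    lambertian_exit_direction,
    sample_free_path,
)


def matched(props_kw=None, **construct_kw):
    """Index-matched construct + properties for analytic-limit tests."""
    ckw = dict(window_n=1.0, gap_medium=GapMedium("air", 0.0, 1.0))
    ckw.update(construct_kw)
    pkw = dict(mu_a=0.0, mu_s=0.0, g=0.0, n=1.0)
    pkw.update(props_kw or {})
    return OpticalProperties(**pkw), SampleConstruct(**ckw)


class TestFreePath:
    def test_analytic_values(self):
        assert sample_free_path(1.0, math.exp(-1)) == pytest.approx(1.0)
        assert sample_free_path(10.01, math.exp(-1)) == pytest.approx(0.0999, abs=1e-4)

    def test_mean_free_path(self):
        rng = np.random.default_rng(3)
        u = rng.random(10**6)
        steps = -np.log(u) / 2.0
        se = steps.std(ddof=1) / np.sqrt(steps.size)
        assert abs(steps.mean() - 0.5) < 3 * se

    def test_rejects_nonpositive_mu_t(self):
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)


class TestLambertian:
    def test_inverse_cdf_polar_angle(self):
        d = lambertian_exit_direction(0.25, 0.1)
        polar = math.degrees(math.asin(math.sqrt(0.25)))
        assert polar == pytest.approx(30.0)
        assert d[2] == pytest.approx(math.cos(math.radians(30.0)))

    def test_cosine_weighted_distribution(self):
        rng = np.random.default_rng(5)
        u1 = rng.random(10**6)
        cos_t = np.sqrt(1.0 - u1)
        se = cos_t.std(ddof=1) / np.sqrt(cos_t.size)
        assert abs(cos_t.mean() - 2.0 / 3.0) < 3 * se
        # histogram of the polar cosine should be proportional to cos(theta)
        hist, edges = np.histogram(cos_t, bins=20, range=(0, 1))
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected = centers / centers.sum() * cos_t.size
        chi2 = np.sum((hist - expected) ** 2 / expected)
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=19) > 0.01


class TestAnalyticLimits:
    def test_vacuum_transmission(self):
        props, construct = matched()
        res = simulate_rt(props, construct, 5000, 1)
        assert res.T_total == 1.0
        assert res.R_diffuse == 0.0

    def test_beer_lambert_nonscattering_slab(self):
        props, construct = matched(dict(mu_a=0.5), sample_thickness=2.0)
        res = simulate_rt(props, construct, 200_000, 2)
        expected = math.exp(-1.0)
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert abs(res.T_total - expected) < 3 * se

    def test_specular_reflectance_of_clear_stack(self):
        # mismatched window: unscattered return is specular, not diffuse
        props = OpticalProperties(0.0, 0.0, 0.0, 1.358)
        construct = SampleConstruct()
        res = simulate_rt(props, construct, 100_000, 3)
        assert res.R_diffuse == 0.0
        assert res.R_specular > 0.03  # ~4% for glass/air at normal incidence
        assert res.T_total == pytest.approx(1.0 - res.R_specular, abs=1e-12)


class TestConservationAndDeterminism:
    @pytest.mark.parametrize(
        "mu_a,mu_s_prime,g,cut,rough",
        [
            (0.03, 1.5, 0.9, 0.0, "smooth"),
            (0.5, 0.5, 0.8, 0.0, "smooth"),
            (0.01, 2.0, 0.99, 0.15, "smooth"),
            (0.05, 1.0, 0.9, 0.0, "lambertian"),
            (0.05, 1.0, 0.9, 0.12, "lambertian"),
        ],
    )
    def test_weight_balance_is_exact(self, mu_a, mu_s_prime, g, cut, rough):
        props = OpticalProperties.from_reduced(mu_a, mu_s_prime, g, 1.358)
        construct = SampleConstruct(cut_fraction=cut, bottom_roughness=rough)
        res = simulate_rt(props, construct, 30_000, 17)
        assert abs(res.balance - 1.0) < 1e-9

    def test_bit_identical_for_same_seed(self):
        props = OpticalProperties.from_reduced(0.03, 1.5, 0.9, 1.358)
        construct = SampleConstruct()
        a = simulate_rt(props, construct, 20_000, 99)
        b = simulate_rt(props, construct, 20_000, 99)
        assert a == b

    def test_different_seeds_differ(self):
        props = OpticalProperties.from_reduced(0.03, 1.5, 0.9, 1.358)
        construct = SampleConstruct()
        a = simulate_rt(props, construct, 5_000, 1)
        b = simulate_rt(props, construct, 5_000, 2)
        assert a.R_diffuse != b.R_diffuse


class TestMonotonicity:
    def test_transmittance_decreases_with_absorption(self):
        construct = SampleConstruct()
        t_vals = []
        for mu_a in [0.01, 0.03, 0.1, 0.3, 1.0]:
            props = OpticalProperties.from_reduced(mu_a, 1.0, 0.9, 1.358)
            t_vals.append(simulate_rt(props, construct, 30_000, 5).T_total)
        assert all(a > b for a, b in zip(t_vals, t_vals[1:]))

    def test_reflectance_increases_with_scattering(self):
        construct = SampleConstruct()
        r_vals = []
        for msp in [0.3, 0.6, 1.2, 2.4, 4.8]:
            props = OpticalProperties.from_reduced(0.01, msp, 0.9, 1.358)
            r_vals.append(simulate_rt(props, construct, 30_000, 5).R_diffuse)
        assert all(a < b for a, b in zip(r_vals, r_vals[1:]))


class TestSimilarityRelation:
    def test_rt_nearly_invariant_in_g_at_fixed_reduced_scattering(self):
        """For g >= 0.8, (R, T) at fixed mu_s' barely depend on g."""
        construct = SampleConstruct()
        res = {}
        for g in (0.8, 0.99):
            props = OpticalProperties.from_reduced(0.01, 1.0, g, 1.358)
            res[g] = simulate_rt(props, construct, 100_000, 21)
        assert abs(res[0.8].R_diffuse - res[0.99].R_diffuse) < 0.01
        assert abs(res[0.8].T_total - res[0.99].T_total) < 0.01


class TestGapMedium:
    def test_absorbing_gap_reduces_transmission(self):
        props = OpticalProperties.from_reduced(0.01, 1.0, 0.9, 1.358)
        clear = SampleConstruct(gap_medium=GapMedium("water", 0.0, 1.33))
        dark = SampleConstruct(gap_medium=GapMedium("water", 5.0, 1.33))
        res_clear = simulate_rt(props, clear, 50_000, 9)
        res_dark = simulate_rt(props, dark, 50_000, 9)
        assert res_dark.A_gap > res_clear.A_gap
        assert res_dark.T_total <= res_clear.T_total

    def test_invalid_inputs_rejected(self):
        props = OpticalProperties.from_reduced(0.01, 1.0, 0.9, 1.358)
        with pytest.raises(ValueError):
            simulate_rt(props, SampleConstruct(), 0, 1)
        with pytest.raises(ValueError):
            SampleConstruct(holder_radius=1.0)


class TestVolumeCut:
    def test_cut_volume_bookkeeping(self):
        c = SampleConstruct(cut_fraction=0.18)
        assert c.true_volume == pytest.approx(c.nominal_volume * 0.82)
        assert c.cut_depth == pytest.approx(0.18 * c.sample_thickness)

    def test_cut_changes_the_physics(self):
        props = OpticalProperties.from_reduced(0.03, 1.5, 0.9, 1.358)
        flat = simulate_rt(props, SampleConstruct(), 50_000, 31)
        cut = simulate_rt(props, SampleConstruct(cut_fraction=0.18), 50_000, 31)
        assert flat.T_total != cut.T_total
        # less tissue in the beam: less sample absorption
        assert cut.A_sample < flat.A_sample
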