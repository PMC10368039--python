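"""Relative-difference reports, quartile bands, normality-gated correlation,
and the setup-parameter sensitivity machinery."""

import numpy as np
import pytest
from scipy import stats

from cartopt.sensitivity import (
    CorrelationResult,
    SensitivityReport,
    g_sensitivity,
    medium_sensitivity,
    normality_check,
    quartile_band,
    relative_difference,
    volume_correlation,
)
from cartopt.spectra import Spectrum

WL = np.arange(500.0, 1301.0, 100.0)


def spec(values):
    return Spectrum(WL, np.asarray(values, float), "mm^-1")


class TestRelativeDifference:
    def test_identity_is_zero(self):
        s = spec(np.linspace(1, 2, WL.size))
        assert np.allclose(relative_difference(s, s).values, 0.0)

    def test_doubling_is_plus_100(self):
        ref = spec(np.linspace(1, 2, WL.size))
        test = ref.with_values(2 * ref.values)
        assert np.allclose(relative_difference(test, ref).values, 100.0)

    def test_halving_is_minus_50(self):
        """Underestimation relative to the reference arm is negative."""
        ref = spec(np.full(WL.size, 0.4))
        test = ref.with_values(0.5 * ref.values)
        assert np.allclose(relative_difference(test, ref).values, -50.0)

    def test_zero_reference_raises(self):
        ref = spec(np.zeros(WL.size))
        with pytest.raises(ZeroDivisionError):
            relative_difference(ref, ref)


class TestQuartileBand:
    def test_single_spectrum_collapses(self):
        s = spec(np.linspace(1, 2, WL.size))
        med, q1, q3 = quartile_band([s])
        assert np.allclose(med.values, s.values)
        assert np.allclose(q1.values, s.values)
        assert np.allclose(q3.values, s.values)

    def test_three_constants(self):
        med, q1, q3 = quartile_band([spec(np.full(WL.size, v)) for v in (1, 2, 3)])
        assert np.allclose(med.values, 2.0)
        assert np.allclose(q1.values, 1.5)
        assert np.allclose(q3.values, 2.5)

    def test_permutation_invariant(self, rng):
        spectra = [spec(rng.random(WL.size)) for _ in range(5)]
        fwd = quartile_band(spectra)
        rev = quartile_band(spectra[::-1])
        for a, b in zip(fwd, rev):
            assert np.allclose(a.values, b.values)

    def test_mixed_axes_rejected(self):
        a = Spectrum(WL, np.ones(WL.size))
        b = Spectrum(WL + 1, np.ones(WL.size))
        with pytest.raises(ValueError):
            quartile_band([a, b])


class TestNormalityCheck:
    def test_gaussian_passes_most_replicates(self):
        passes = 0
        for rep in range(100):
            x = np.random.default_rng(rep).normal(size=500)
            passes += normality_check(x)[0]
        assert passes >= 90

    def test_exponential_fails_most_replicates(self):
        fails = 0
        for rep in range(100):
            x = np.random.default_rng(rep).exponential(size=500)
            fails += not normality_check(x)[0]
        assert fails >= 90

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0] * 10)


class TestVolumeCorrelation:
    def test_perfect_linear_relationship(self, rng):
        x = rng.normal(size=30)
        res = volume_correlation(x, 2.0 * x + 1.0, mode="absolute")
        assert res.phi == pytest.approx(1.0)
        assert res.p_value < 1e-3
        assert res.method == "pearson"

    def test_rank_oracle_for_nonnormal_data(self):
        # skewed marginals force the rank-based branch
        x = np.array([1.0, 2, 3, 4, 5, 60, 70, 800, 900, 10000])
        y = np.array([5.0, 1, 4, 2, 3, 700, 60, 90, 8000, 10])
        res = volume_correlation(x, y)
        assert res.method == "spearman"
        # brute-force rank correlation
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert res.phi == pytest.approx(brute)

    def test_null_simulation_is_calibrated(self):
        """Independent normal pairs: phi near 0 and p-values uniform."""
        p_values = np.empty(1000)
        phis = np.empty(1000)
        for rep in range(1000):
            rng = np.random.default_rng(10_000 + rep)
            res = volume_correlation(rng.normal(size=60), rng.normal(size=60))
            p_values[rep] = res.p_value
            phis[rep] = res.phi
        assert np.median(np.abs(phis)) < 0.15
        assert stats.kstest(p_values, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            volume_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestReportStructure:
    def test_quartile_ordering_enforced(self):
        with pytest.raises(ValueError):
            SensitivityReport(
                wavelengths=WL,
                rel_diff_median=np.zeros(WL.size),
                rel_diff_q1=np.ones(WL.size),
                rel_diff_q3=np.zeros(WL.size),
                factor="g",
                levels=(0.8, 0.9),
            )

    def test_correlation_result_invariants(self):
        with pytest.raises(ValueError):
            CorrelationResult(phi=1.5, p_value=0.1, method="pearson", n=10)
        with pytest.raises(ValueError):
            CorrelationResult(phi=0.5, p_value=0.1, method="pearson", n=2)


class TestSensitivityOnAnalyticTables:
    """Fast checks of the factor-sweep plumbing on noise-free tables."""

    def _record(self, analytic_lut):
        from cartopt.records import MeasurementRecord

        a = np.geomspace(5e-3, 0.3, WL.size)
        s = np.geomspace(0.5, 2.5, WL.size)
        R, T = analytic_lut.predict(a, s)
        return MeasurementRecord(WL, np.clip(R, 0, 1), np.clip(T, 0, 1))

    def test_identical_tables_give_zero_difference(self, analytic_lut):
        record = self._record(analytic_lut)
        reports, correlations = g_sensitivity(
            record, {0.8: analytic_lut, 0.9: analytic_lut, 0.99: analytic_lut}
        )
        for report in reports.values():
            assert report.median_abs() < 1e-3
        for corr in correlations.values():
            assert corr.phi == pytest.approx(1.0, abs=1e-6)

    def test_missing_baseline_rejected(self, analytic_lut):
        record = self._record(analytic_lut)
        with pytest.raises(ValueError):
            g_sensitivity(record, {0.8: analytic_lut}, baseline_g=0.9)

    def test_identical_medium_tables_give_identical_reports(self, analytic_lut):
        record = self._record(analytic_lut)
        theoretical = Spectrum(WL, np.geomspace(5e-3, 0.3, WL.size), "mm^-1")
        reports = medium_sensitivity(record, analytic_lut, analytic_lut, theoretical)
        assert np.allclose(
            reports["air"].rel_diff_median, reports["water"].rel_diff_median
        )
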