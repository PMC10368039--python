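"""Sensitivity of the recovered optical properties to setup parameters:
surrounding medium, anisotropy factor, refractive index, bottom-surface
roughness, and sample-volume irregularity; plus the summary statistics
(quartile bands, normality-gated correlation).

Convention: relative differences are always computed against the second
argument (the reference arm: theoretical mu_a, the g = 0.9 arm, the smooth
arm, or the baseline-n arm), in percent, so underestimation is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inversion import invert_rt
from .lut import LookupTable
from .model import invert_spectrum
from .montecarlo import SampleConstruct, simulate_rt
from .records import MeasurementRecord
from .spectra import OpticalProperties, Spectrum

__all__ = [
    "SensitivityReport",
    "CorrelationResult",
    "relative_difference",
    "quartile_band",
    "normality_check",
    "volume_correlation",
    "g_sensitivity",
    "medium_sensitivity",
    "roughness_experiment",
]


@dataclass(frozen=True)
class SensitivityReport:
    """Per-wavelength relative-difference quartile band for one factor."""

    wavelengths: np.ndarray
    rel_diff_median: np.ndarray  # percent
    rel_diff_q1: np.ndarray
    rel_diff_q3: np.ndarray
    factor: str  # medium | g | n | roughness
    levels: tuple  # (test level, reference level)
    property_name: str = ""

    def __post_init__(self) -> None:
        if np.any(self.rel_diff_q1 > self.rel_diff_median + 1e-12) or np.any(
            self.rel_diff_median > self.rel_diff_q3 + 1e-12
        ):
            raise ValueError("quartile band must satisfy q1 <= median <= q3")

    def median_abs(self, band: tuple[float, float] | None = None) -> float:
        """Median over wavelengths of |relative difference|, percent."""
        m = np.abs(self.rel_diff_median)
        if band is not None:
            sel = (self.wavelengths >= band[0]) & (self.wavelengths <= band[1])
            m = m[sel]
        return float(np.median(m))

    def max_abs(self, band: tuple[float, float] | None = None) -> float:
        m = np.abs(self.rel_diff_median)
        if band is not None:
            sel = (self.wavelengths >= band[0]) & (self.wavelengths <= band[1])
            m = m[sel]
        return float(np.max(m))


@dataclass(frozen=True)
class CorrelationResult:
    phi: float
    p_value: float
    method: str  # pearson | spearman
    n: int

    def __post_init__(self) -> None:
        if abs(self.phi) > 1 + 1e-12:
            raise ValueError("|phi| must be <= 1")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


def relative_difference(test: Spectrum, reference: Spectrum) -> Spectrum:
    """100 * (test - reference) / reference, percent, pointwise."""
    test.require_same_axis(reference)
    if np.any(reference.values == 0):
        bad = test.wavelengths[reference.values == 0]
        raise ZeroDivisionError(
            f"reference is zero at wavelength(s) {bad[:3].tolist()} nm"
        )
    return Spectrum(
        test.wavelengths,
        100.0 * (test.values - reference.values) / reference.values,
        "percent",
    )


def quartile_band(spectra: list[Spectrum]) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Pointwise median and 1st/3rd quartiles (linear-interpolation quantiles)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        first.require_same_axis(s)
    stack = np.vstack([s.values for s in spectra])
    med = np.quantile(stack, 0.5, axis=0)
    q1 = np.quantile(stack, 0.25, axis=0)
    q3 = np.quantile(stack, 0.75, axis=0)
    u = first.units_tag
    wl = first.wavelengths
    return Spectrum(wl, med, u), Spectrum(wl, q1, u), Spectrum(wl, q3, u)


def normality_check(x, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk normality check at the given alpha.

    Returns (passes, W statistic).  Raises on constant or too-short input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("normality check undefined for a constant vector")
    stat, p = stats.shapiro(x)
    return bool(p > alpha), float(stat)


def volume_correlation(volume_diff, mu_a_diff, mode: str = "relative") -> CorrelationResult:
    """Correlation between per-sample volume deviation and mu_a deviation.

    Pearson when both variables pass the normality check, Spearman
    otherwise — mirroring a normality-gated parametric/rank test choice.
    ``mode`` records whether the inputs are absolute (mm^3) or relative
    (percent) deviations; it does not change the computation.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    x = np.asarray(volume_diff, dtype=float)
    y = np.asarray(mu_a_diff, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    use_pearson = normality_check(x)[0] and normality_check(y)[0]
    if use_pearson:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(phi=float(r), p_value=float(p), method=method, n=int(x.size))


def _auto_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    try:
        use_pearson = normality_check(x)[0] and normality_check(y)[0]
    except ValueError:
        use_pearson = False
    if use_pearson:
        r, p = stats.pearsonr(x, y)
        return CorrelationResult(float(r), float(p), "pearson", int(x.size))
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), "spearman", int(x.size))


def _collapse_band(wl: np.ndarray, curves: list[np.ndarray], factor: str, levels: tuple, prop: str) -> SensitivityReport:
    stack = np.vstack(curves)
    return SensitivityReport(
        wavelengths=wl,
        rel_diff_median=np.quantile(stack, 0.5, axis=0),
        rel_diff_q1=np.quantile(stack, 0.25, axis=0),
        rel_diff_q3=np.quantile(stack, 0.75, axis=0),
        factor=factor,
        levels=levels,
        property_name=prop,
    )


def g_sensitivity(
    records,
    luts_by_g: dict,
    baseline_g: float = 0.9,
):
    """Invert records under each anisotropy assumption and compare.

    ``records`` is one MeasurementRecord or a list; ``luts_by_g`` maps g to
    a LookupTable sharing grid and construct.  Returns
    (reports, correlations): reports keyed by (property, g) with relative
    differences against the baseline-g arm; correlations keyed likewise with
    the correlation between the property spectra of the two arms.
    """
    if baseline_g not in luts_by_g:
        raise ValueError(f"missing baseline g level {baseline_g}")
    if isinstance(records, MeasurementRecord):
        records = [records]
    g_levels = sorted(luts_by_g)
    fits = {
        g: [invert_spectrum(rec, luts_by_g[g]) for rec in records] for g in g_levels
    }
    wl = records[0].wavelengths
    reports: dict = {}
    correlations: dict = {}
    for g in g_levels:
        if g == baseline_g:
            continue
        for prop, idx in (("mu_a", 0), ("mu_s_prime", 1)):
            curves = []
            for fit_g, fit_base in zip(fits[g], fits[baseline_g]):
                curves.append(
                    relative_difference(fit_g[idx], fit_base[idx]).values
                )
            reports[(prop, g)] = _collapse_band(
                wl, curves, "g", (g, baseline_g), prop
            )
            test_vals = np.concatenate([f[idx].values for f in fits[g]])
            base_vals = np.concatenate([f[idx].values for f in fits[baseline_g]])
            correlations[(prop, g)] = _auto_correlation(test_vals, base_vals)
    return reports, correlations


def medium_sensitivity(
    records,
    lut_air: LookupTable,
    lut_water: LookupTable,
    mu_a_theoretical: Spectrum,
):
    """Invert records assuming air vs water in the lateral gap.

    Returns a report per medium: relative difference of the recovered mu_a
    from the theoretical mixture reference.
    """
    if isinstance(records, MeasurementRecord):
        records = [records]
    wl = records[0].wavelengths
    if not np.array_equal(wl, mu_a_theoretical.wavelengths):
        raise ValueError("theoretical reference must share the record axis")
    reports = {}
    for label, lut in (("air", lut_air), ("water", lut_water)):
        curves = [
            relative_difference(invert_spectrum(rec, lut)[0], mu_a_theoretical).values
            for rec in records
        ]
        reports[label] = _collapse_band(
            wl, curves, "medium", (label, "theoretical"), "mu_a"
        )
    return reports


def roughness_experiment(
    props: OpticalProperties,
    construct: SampleConstruct,
    lut_smooth: LookupTable,
    n_photons: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percent change of recovered (mu_a, mu_s') from maximal bottom roughness.

    Simulates the construct with a smooth and a fully Lambertian bottom
    interface (common random numbers), inverts both against the smooth-
    geometry table, and returns 100 * (rough - smooth)/smooth for each
    recovered property.
    """
    smooth = construct.with_(bottom_roughness="smooth")
    rough = construct.with_(bottom_roughness="lambertian")
    res_s = simulate_rt(props, smooth, n_photons, seed)
    res_r = simulate_rt(props, rough, n_photons, seed)
    inv_s = invert_rt(res_s.R_diffuse, res_s.T_total, lut_smooth)
    inv_r = invert_rt(res_r.R_diffuse, res_r.T_total, lut_smooth)
    d_mu_a = 100.0 * (inv_r.mu_a_hat - inv_s.mu_a_hat) / inv_s.mu_a_hat
    d_mu_s = 100.0 * (inv_r.mu_s_prime_hat - inv_s.mu_s_prime_hat) / inv_s.mu_s_prime_hat
    return float(d_mu_a), float(d_mu_s)
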