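"""Theoretical absorption of cartilage as a chromophore mixture, and the
observation-removal (QC) filter for estimated absorption spectra.

The tissue is modelled as a volume mixture of water, collagen, elastin and
lipid; the theoretical absorption coefficient is the fraction-weighted sum
of the component spectra.  Estimated mu_a spectra that are flat, implausibly
low (<= 1e-5 mm^-1) or missing the characteristic near-infrared features of
the theoretical reference are flagged for removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import Spectrum

__all__ = [
    "DEFAULT_FRACTIONS",
    "ComponentLibrary",
    "QCDecision",
    "default_component_library",
    "mixture_absorption",
    "qc_filter",
]

COMPONENTS = ("water", "collagen", "elastin", "lipid")

#: Cartilage matrix volume fractions: water 68%, collagen 30%, elastin 1%,
#: lipid 1%.
DEFAULT_FRACTIONS = {"water": 0.68, "collagen": 0.30, "elastin": 0.01, "lipid": 0.01}

MU_A_FLOOR = 1e-5  # mm^-1; estimates at or below this are signal distortion
FEATURE_BAND = (900.0, 1400.0)  # nm; where the water features live


@dataclass(frozen=True)
class ComponentLibrary:
    """Absorption spectra of the tissue constituents plus volume fractions."""

    spectra: dict  # name -> Spectrum (mm^-1)
    fractions: dict  # name -> volume fraction

    def __post_init__(self) -> None:
        if set(self.spectra) != set(self.fractions):
            raise ValueError("spectra and fractions must list the same components")
        fr = np.array([self.fractions[c] for c in self.spectra], dtype=float)
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fr.sum()!r}")
        names = list(self.spectra)
        first = self.spectra[names[0]]
        for name in names[1:]:
            first.require_same_axis(self.spectra[name])

    @property
    def wavelengths(self) -> np.ndarray:
        return next(iter(self.spectra.values())).wavelengths

    def with_fractions(self, fractions: dict) -> "ComponentLibrary":
        return ComponentLibrary(self.spectra, dict(fractions))


def mixture_absorption(lib: ComponentLibrary) -> Spectrum:
    """Fraction-weighted sum of component absorption spectra (mm^-1)."""
    total = np.zeros_like(lib.wavelengths, dtype=float)
    for name, spec in lib.spectra.items():
        total += lib.fractions[name] * spec.values
    return Spectrum(lib.wavelengths, total, "mm^-1")


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_component_library(
    wavelengths, fractions: dict | None = None
) -> ComponentLibrary:
    """Synthetic stand-in component spectra on the given axis.

    These curves are generated, not measured: the water stand-in is a smooth
    low baseline with absorption bands near 970, 1200 and 1400 nm (the
    magnitudes are water-like, rising to ~1 mm^-1 at 1400 nm); collagen and
    elastin are monotone decreasing power laws and lipid a weak monotone
    rising curve.  Real literature spectra can be supplied instead through
    :func:`cartopt.io.read_component_library`.
    """
    wl = np.asarray(wavelengths, dtype=float)
    water = (
        0.002
        + _gauss(wl, 740.0, 25.0, 0.0025)
        + _gauss(wl, 970.0, 35.0, 0.045)
        + _gauss(wl, 1200.0, 45.0, 0.10)
        + _gauss(wl, 1440.0, 55.0, 1.6)
    )
    collagen = 0.12 * (wl / 400.0) ** -1.8 + 0.01
    elastin = 0.08 * (wl / 400.0) ** -1.5 + 0.005
    lipid = 0.004 + 0.010 * (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)
    spectra = {
        "water": Spectrum(wl, water, "mm^-1"),
        "collagen": Spectrum(wl, collagen, "mm^-1"),
        "elastin": Spectrum(wl, elastin, "mm^-1"),
        "lipid": Spectrum(wl, lipid, "mm^-1"),
    }
    return ComponentLibrary(spectra, dict(fractions or DEFAULT_FRACTIONS))


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reasons: frozenset

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be True exactly when reasons is empty")


def qc_filter(
    mu_a_est: Spectrum,
    mu_a_theoretical: Spectrum,
    floor: float = MU_A_FLOOR,
    cv_min: float = 0.05,
    r_min: float = 0.5,
    feature_band: tuple[float, float] = FEATURE_BAND,
) -> QCDecision:
    """Observation-removal filter for an estimated absorption spectrum.

    Fails with

    - ``below_floor`` if any mu_a value is <= ``floor`` (default 1e-5 mm^-1),
    - ``flat_signal`` if the coefficient of variation over the band is
      below ``cv_min``,
    - ``missing_features`` if the Pearson correlation with the theoretical
      mixture over ``feature_band`` is below ``r_min``.

    The spectrum is kept iff no check fails.
    """
    mu_a_est.require_same_axis(mu_a_theoretical)
    if len(mu_a_est) < 3:
        raise ValueError("QC needs at least 3 wavelengths")
    reasons = set()
    vals = mu_a_est.values
    if np.any(vals <= floor):
        reasons.add("below_floor")
    mean = vals.mean()
    cv = vals.std(ddof=0) / abs(mean) if mean != 0 else np.inf
    if cv < cv_min:
        reasons.add("flat_signal")
    est_band = mu_a_est.band(*feature_band)
    theo_band = mu_a_theoretical.band(*feature_band)
    if len(est_band) < 3:
        raise ValueError(
            f"feature band {feature_band} covers fewer than 3 wavelengths"
        )
    if np.ptp(est_band.values) == 0 or np.ptp(theo_band.values) == 0:
        reasons.add("missing_features")
    else:
        r, _ = stats.pearsonr(est_band.values, theo_band.values)
        if r < r_min:
            reasons.add("missing_features")
    return QCDecision(keep=not reasons, reasons=frozenset(reasons))
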