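"""Wavelength-resolved spectra and per-medium optical properties.

The package works in millimetres throughout: absorption and scattering
coefficients are mm^-1, wavelengths are nm.  A :class:`Spectrum` is a thin
validated container around a pair of numpy arrays; arithmetic convenience is
intentionally minimal — analyses operate on the ``.values`` arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Spectrum", "OpticalProperties", "UNITS_TAGS"]

UNITS_TAGS = ("mm^-1", "fraction", "percent", "dimensionless")


@dataclass(frozen=True)
class Spectrum:
    """A per-wavelength scalar curve on a strictly increasing nm axis."""

    wavelengths: np.ndarray
    values: np.ndarray
    units_tag: str = "dimensionless"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"axis/value length mismatch: {wl.size} != {vals.size}"
            )
        if wl.size and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.units_tag not in UNITS_TAGS:
            raise ValueError(f"unknown units_tag {self.units_tag!r}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def same_axis(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.allclose(
            self.wavelengths, other.wavelengths, atol=atol
        )

    def require_same_axis(self, other: "Spectrum") -> None:
        if not self.same_axis(other):
            raise ValueError("spectra do not share a wavelength axis")

    def with_values(self, values: np.ndarray, units_tag: str | None = None) -> "Spectrum":
        return replace(
            self, values=np.asarray(values, float),
            units_tag=self.units_tag if units_tag is None else units_tag,
        )

    def band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Restrict to wavelengths in [lo_nm, hi_nm] (inclusive)."""
        m = (self.wavelengths >= lo_nm) & (self.wavelengths <= hi_nm)
        return Spectrum(self.wavelengths[m], self.values[m], self.units_tag)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Single scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy factor (mean cosine of deflection), |g| < 1.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must be in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Attenuation coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @classmethod
    def from_reduced(cls, mu_a: float, mu_s_prime: float, g: float, n: float) -> "OpticalProperties":
        """Build from (mu_a, mu_s') with mu_s = mu_s' / (1 - g)."""
        if mu_s_prime < 0:
            raise ValueError("mu_s_prime must be >= 0")
        return cls(mu_a=mu_a, mu_s=mu_s_prime / (1.0 - g), g=g, n=n)
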