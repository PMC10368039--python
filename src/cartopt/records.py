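"""Measurement records: paired reflectance/transmittance spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum

__all__ = ["MeasurementRecord"]


@dataclass(frozen=True)
class MeasurementRecord:
    """Paired calibrated R and T spectra for one sample.

    R and T are stored as fractions in [0, 1] on a shared, strictly
    increasing wavelength axis (nm).
    """

    wavelengths: np.ndarray
    R: np.ndarray
    T: np.ndarray
    site: str = ""
    sample_id: str = ""
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.R, dtype=float)
        t = np.asarray(self.T, dtype=float)
        if not (wl.size == r.size == t.size):
            raise ValueError("wavelengths, R and T must have equal lengths")
        if wl.size and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.size and (not np.all(np.isfinite(r)) or not np.all(np.isfinite(t))):
            raise ValueError("R and T must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "R", r)
        object.__setattr__(self, "T", t)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def R_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths, self.R, "fraction")

    @property
    def T_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths, self.T, "fraction")
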