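"""Spectral inversion as a fitted model.

:class:`SpectralInversion` plays the role a regression model class plays in
statsmodels: it is constructed from data (a :class:`MeasurementRecord`) and
a forward model (per-wavelength lookup tables), and :meth:`fit` returns a
:class:`SpectralInversionResults` object carrying the estimated absorption
and reduced-scattering spectra, their delta-method standard errors, fit
diagnostics, QC, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .inversion import InversionResult, invert_rt
from .lut import LookupTable
from .mixture import QCDecision, qc_filter
from .records import MeasurementRecord
from .spectra import Spectrum

__all__ = ["SpectralInversion", "SpectralInversionResults", "invert_spectrum"]


def _lut_for(luts, wavelength: float) -> LookupTable:
    if isinstance(luts, LookupTable):
        return luts
    if isinstance(luts, Mapping):
        if wavelength in luts:
            return luts[wavelength]
        # tolerate float-key round-off
        keys = np.array(sorted(luts.keys()), dtype=float)
        hit = keys[np.isclose(keys, wavelength, atol=1e-6)]
        if hit.size:
            return luts[float(hit[0])]
        raise KeyError(f"no lookup table for wavelength {wavelength} nm")
    raise TypeError("luts must be a LookupTable or a {wavelength: LookupTable} mapping")


def invert_spectrum(record: MeasurementRecord, luts):
    """Per-wavelength inversion of a record.

    ``luts`` is either one :class:`LookupTable` (applied at every
    wavelength; valid when the geometry and media are achromatic over the
    band) or a mapping wavelength -> table.  Returns (mu_a spectrum,
    mu_s' spectrum, list of per-wavelength :class:`InversionResult`).
    """
    mu_a = np.empty(len(record))
    mu_s = np.empty(len(record))
    details: list[InversionResult] = []
    for i, wl in enumerate(record.wavelengths):
        lut = _lut_for(luts, float(wl))
        res = invert_rt(float(record.R[i]), float(record.T[i]), lut)
        mu_a[i] = res.mu_a_hat
        mu_s[i] = res.mu_s_prime_hat
        details.append(res)
    return (
        Spectrum(record.wavelengths, mu_a, "mm^-1"),
        Spectrum(record.wavelengths, mu_s, "mm^-1"),
        details,
    )


class SpectralInversion:
    """Model: measured (R, T) spectra explained by a lookup-table forward model.

    Parameters
    ----------
    record : MeasurementRecord
        Calibrated diffuse reflectance / total transmittance spectra.
    luts : LookupTable or mapping
        Forward-model table(s); one table may serve all wavelengths.
    """

    def __init__(self, record: MeasurementRecord, luts) -> None:
        self.record = record
        self.luts = luts

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, luts, **record_kw) -> "SpectralInversion":
        """Build from a frame with columns wavelength_nm, R, T (fractions)."""
        required = {"wavelength_nm", "R", "T"}
        if not required.issubset(frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        frame = frame.sort_values("wavelength_nm")
        rec = MeasurementRecord(
            wavelengths=frame["wavelength_nm"].to_numpy(float),
            R=frame["R"].to_numpy(float),
            T=frame["T"].to_numpy(float),
            **record_kw,
        )
        return cls(rec, luts)

    def fit(self) -> "SpectralInversionResults":
        mu_a, mu_s, details = invert_spectrum(self.record, self.luts)
        return SpectralInversionResults(model=self, mu_a=mu_a, mu_s_prime=mu_s, details=details)


@dataclass
class SpectralInversionResults:
    """Estimated optical-property spectra and per-wavelength diagnostics."""

    model: SpectralInversion
    mu_a: Spectrum
    mu_s_prime: Spectrum
    details: list[InversionResult]
    qc: QCDecision | None = field(default=None)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.mu_a.wavelengths

    @property
    def on_boundary(self) -> np.ndarray:
        return np.array([d.on_boundary for d in self.details], dtype=bool)

    @property
    def converged(self) -> np.ndarray:
        return np.array([d.converged for d in self.details], dtype=bool)

    @property
    def residuals(self) -> np.ndarray:
        return np.array([d.residual for d in self.details], dtype=float)

    @property
    def se_mu_a(self) -> np.ndarray:
        return np.array([d.se_mu_a for d in self.details], dtype=float)

    @property
    def se_mu_s_prime(self) -> np.ndarray:
        return np.array([d.se_mu_s_prime for d in self.details], dtype=float)

    def run_qc(self, mu_a_theoretical: Spectrum, **params) -> QCDecision:
        """Apply the observation-removal filter to the estimated mu_a."""
        self.qc = qc_filter(self.mu_a, mu_a_theoretical, **params)
        return self.qc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "mu_a": self.mu_a.values,
                "se_mu_a": self.se_mu_a,
                "mu_s_prime": self.mu_s_prime.values,
                "se_mu_s_prime": self.se_mu_s_prime,
                "residual": self.residuals,
                "on_boundary": self.on_boundary,
            }
        )

    def summary(self) -> str:
        rec = self.model.record
        frame = self.to_frame()
        head = [
            "Spectral inversion of integrating-sphere R/T",
            "=" * 52,
            f"sample id      : {rec.sample_id or '-'}   site: {rec.site or '-'}",
            f"wavelengths    : {len(rec)} points "
            f"[{rec.wavelengths[0]:.0f}, {rec.wavelengths[-1]:.0f}] nm"
            if len(rec)
            else "wavelengths    : 0 points",
            f"on-boundary    : {int(self.on_boundary.sum())} / {len(rec)}",
            f"median residual: {np.median(self.residuals):.3g}" if len(rec) else "",
        ]
        if self.qc is not None:
            head.append(
                f"QC             : {'keep' if self.qc.keep else 'remove'} "
                f"{sorted(self.qc.reasons) if self.qc.reasons else ''}"
            )
        body = frame.to_string(
            index=False,
            float_format=lambda v: f"{v:.5g}",
            columns=["wavelength_nm", "mu_a", "se_mu_a", "mu_s_prime", "se_mu_s_prime", "on_boundary"],
        )
        return "\n".join([line for line in head if line] + ["-" * 52, body])
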