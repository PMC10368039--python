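"""Delimited-text spectrum tables, component libraries and run provenance.

Spectrum tables have a ``wavelength_nm`` header column plus one column per
spectrum; comma- and tab-delimited dialects are both accepted, with a
decimal point.  Rows are written sorted by wavelength, so write-then-read is
the identity up to float round-trip.
"""

from __future__ import annotations

import hashlib
import json


import numpy as np
import pandas as pd

from .mixture import ComponentLibrary
from .spectra import Spectrum

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "read_component_library",
    "write_component_library",
    "config_hash",
]


def _read_table(path) -> pd.DataFrame:
    # sep=None triggers python-engine sniffing: handles comma and tab alike
    frame = pd.read_csv(path, sep=None, engine="python")
    if "wavelength_nm" not in frame.columns:
        raise ValueError(f"{path}: missing 'wavelength_nm' header column")
    wl = frame["wavelength_nm"].to_numpy(float)
    dup = np.flatnonzero(np.diff(np.sort(wl)) == 0)
    if dup.size:
        raise ValueError(
            f"{path}: duplicated wavelength {np.sort(wl)[dup[0]]} nm "
            f"(first duplicate at sorted row {dup[0] + 1})"
        )
    return frame.sort_values("wavelength_nm").reset_index(drop=True)


def read_spectrum_table(path, units_tag: str = "dimensionless") -> dict[str, Spectrum]:
    """Read all value columns of a delimited spectrum table."""
    frame = _read_table(path)
    wl = frame["wavelength_nm"].to_numpy(float)
    out = {}
    for col in frame.columns:
        if col == "wavelength_nm":
            continue
        out[col] = Spectrum(wl, frame[col].to_numpy(float), units_tag)
    if not out:
        raise ValueError(f"{path}: no value columns")
    return out


def write_spectrum_table(spectra: dict[str, Spectrum], path, sep: str = ",") -> None:
    """Write named spectra sharing one axis, sorted by wavelength."""
    names = list(spectra)
    first = spectra[names[0]]
    for name in names[1:]:
        first.require_same_axis(spectra[name])
    order = np.argsort(first.wavelengths)
    frame = pd.DataFrame({"wavelength_nm": first.wavelengths[order]})
    for name in names:
        frame[name] = spectra[name].values[order]
    frame.to_csv(path, sep=sep, index=False)


def read_component_library(path, fractions: dict) -> ComponentLibrary:
    """Component library from a table with water/collagen/elastin/lipid columns."""
    spectra = read_spectrum_table(path, units_tag="mm^-1")
    missing = set(fractions) - set(spectra)
    if missing:
        raise ValueError(f"{path}: missing component columns {sorted(missing)}")
    return ComponentLibrary({c: spectra[c] for c in fractions}, dict(fractions))


def write_component_library(lib: ComponentLibrary, path, sep: str = ",") -> None:
    write_spectrum_table(dict(lib.spectra), path, sep=sep)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for artifact provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
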