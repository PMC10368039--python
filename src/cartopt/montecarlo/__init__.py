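"""Monte Carlo forward model of the integrating-sphere sample construct.

A cylindrical tissue sample sits in a glass cuvette between two clear
windows; the lateral gap between sample and holder wall is filled with air
or water.  :func:`simulate_rt` transports photon packets through this
construct and tallies diffuse reflectance, total transmittance, absorption
and side loss, with Monte Carlo standard errors and exact weight
bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ..spectra import OpticalProperties
from . import kernel as _k

__all__ = [
    "GapMedium",
    "SampleConstruct",
    "RTResult",
    "simulate_rt",
    "sample_free_path",
    "lambertian_exit_direction",
    "AIR",
    "WATER",
]

# roulette defaults: variance-safe termination of low-weight packets
ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class GapMedium:
    """Medium filling the lateral sample/holder gap (and any cut pocket)."""

    name: str
    mu_a: float = 0.0  # mm^-1 at the simulated wavelength
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("gap mu_a must be >= 0")
        if self.n < 1.0:
            raise ValueError("gap n must be >= 1")


AIR = GapMedium("air", mu_a=0.0, n=1.0)
WATER = GapMedium("water", mu_a=0.0, n=1.33)


@dataclass(frozen=True)
class SampleConstruct:
    """Cylinder-in-holder geometry.  All lengths in mm.

    ``cut_fraction`` is the relative volume deficit of the sample from a
    perfect cylinder, realized as a planar oblique truncation of the bottom
    face (depth ``cut_fraction * thickness`` at maximal tilt).
    """

    sample_radius: float = 7.0
    sample_thickness: float = 2.0
    window_thickness: float = 1.0
    window_n: float = 1.52
    gap_medium: GapMedium = AIR
    holder_radius: float = 9.0
    bottom_roughness: str = "smooth"  # or "lambertian"
    beam_radius: float = 1.0
    cut_fraction: float = 0.0
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sample_radius", "sample_thickness", "window_thickness", "beam_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.holder_radius < self.sample_radius:
            raise ValueError("holder_radius must be >= sample_radius")
        if self.bottom_roughness not in ("smooth", "lambertian"):
            raise ValueError("bottom_roughness must be 'smooth' or 'lambertian'")
        if not 0.0 <= self.cut_fraction < 1.0:
            raise ValueError("cut_fraction must lie in [0, 1)")
        if self.window_n < 1.0 or self.ambient_n < 1.0:
            raise ValueError("refractive indices must be >= 1")

    @property
    def nominal_volume(self) -> float:
        """Perfect-cylinder volume, mm^3."""
        return math.pi * self.sample_radius**2 * self.sample_thickness

    @property
    def true_volume(self) -> float:
        """Sample volume after the oblique bottom truncation, mm^3."""
        return self.nominal_volume * (1.0 - self.cut_fraction)

    @property
    def cut_depth(self) -> float:
        return self.cut_fraction * self.sample_thickness

    @property
    def cut_slope(self) -> float:
        # maximal tilt keeping the plane inside the cylinder height
        return self.cut_depth / self.sample_radius

    def with_(self, **kw) -> "SampleConstruct":
        return replace(self, **kw)


@dataclass(frozen=True)
class RTResult:
    """Tallies of one forward simulation, as fractions of launched weight."""

    R_diffuse: float
    T_total: float
    A_sample: float
    A_gap: float
    R_specular: float
    side_loss: float
    roulette_net: float
    se_R: float
    se_T: float
    n_photons: int
    seed: int
    mean_scatter_events: float = 0.0

    @property
    def balance(self) -> float:
        """Total bookkept weight; equals 1 to float precision."""
        return (
            self.R_diffuse
            + self.T_total
            + self.A_sample
            + self.A_gap
            + self.R_specular
            + self.side_loss
            + self.roulette_net
        )

    def as_row(self) -> dict:
        return {
            "R_diffuse": self.R_diffuse,
            "T_total": self.T_total,
            "A_sample": self.A_sample,
            "A_gap": self.A_gap,
            "R_specular": self.R_specular,
            "side_loss": self.side_loss,
            "roulette_net": self.roulette_net,
            "se_R": self.se_R,
            "se_T": self.se_T,
            "n_photons": self.n_photons,
            "seed": self.seed,
        }


def sample_free_path(mu_t: float, u: float) -> float:
    """Exponential free path -ln(u)/mu_t (mm) for attenuation mu_t (mm^-1)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    return -math.log(u) / mu_t


def lambertian_exit_direction(u1: float, u2: float) -> tuple[float, float, float]:
    """Cosine-weighted unit direction about the +z axis.

    Polar angle theta = arcsin(sqrt(u1)) so that the exit density is
    proportional to cos(theta); azimuth is 2*pi*u2.
    """
    if not (0.0 < u1 < 1.0 and 0.0 < u2 < 1.0):
        raise ValueError("u1, u2 must lie in (0, 1)")
    sin_t = math.sqrt(u1)
    cos_t = math.sqrt(1.0 - u1)
    phi = 2.0 * math.pi * u2
    return (sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t)


def simulate_rt(
    props: OpticalProperties,
    construct: SampleConstruct,
    n_photons: int,
    seed: int,
) -> RTResult:
    """Forward-simulate diffuse reflectance and total transmittance.

    A collimated top-hat beam enters the top window at normal incidence.
    Diffuse weight escaping through the top is tallied as reflectance (the
    unscattered specular return is tallied separately and excluded); all
    weight escaping through the bottom is total transmittance.  Identical
    inputs and seed give bit-identical tallies.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    tal = _k.transport(
        int(n_photons),
        int(seed) & 0xFFFFFFFFFFFFFFFF,
        float(props.mu_a),
        float(props.mu_s),
        float(props.g),
        float(props.n),
        float(construct.gap_medium.mu_a),
        float(construct.gap_medium.n),
        float(construct.window_n),
        float(construct.ambient_n),
        float(construct.window_thickness),
        float(construct.window_thickness),
        float(construct.sample_thickness),
        float(construct.sample_radius),
        float(construct.holder_radius),
        float(construct.beam_radius),
        float(construct.cut_depth),
        float(construct.cut_slope),
        1 if construct.bottom_roughness == "lambertian" else 0,
        ROULETTE_WEIGHT,
        ROULETTE_SURVIVAL,
    )
    n = float(n_photons)
    r = tal[_k.T_RDIFF] / n
    t = tal[_k.T_TTOT] / n
    var_r = max(0.0, tal[_k.T_SUMR2] / n - r * r)
    var_t = max(0.0, tal[_k.T_SUMT2] / n - t * t)
    return RTResult(
        R_diffuse=r,
        T_total=t,
        A_sample=tal[_k.T_ASAMP] / n,
        A_gap=tal[_k.T_AGAP] / n,
        R_specular=tal[_k.T_RSPEC] / n,
        side_loss=tal[_k.T_SIDE] / n,
        roulette_net=tal[_k.T_ROULETTE] / n,
        se_R=math.sqrt(var_r / n),
        se_T=math.sqrt(var_t / n),
        n_photons=int(n_photons),
        seed=int(seed),
        mean_scatter_events=tal[_k.T_NSCAT] / n,
    )
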