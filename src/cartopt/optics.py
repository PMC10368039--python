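"""Radiometric primitives: Henyey-Greenstein phase function and sampler,
reduced scattering, unpolarized Fresnel reflectance.

These are the scalar/vectorized reference implementations; the Monte Carlo
kernel re-implements the same formulas inline under numba (see
``cartopt.montecarlo.kernel``), and the test suite checks the two against
each other.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hg_phase",
    "sample_hg_cosine",
    "reduced_scattering",
    "fresnel_unpolarized",
]


def _check_g(g: float) -> None:
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy factor g must satisfy |g| < 1, got {g}")


def hg_phase(theta, g):
    """Henyey-Greenstein phase function p(theta; g), per steradian.

    p(theta) = (1/4pi) (1 - g^2) / (1 + g^2 - 2 g cos(theta))^(3/2)

    normalised so that the integral over the unit sphere is 1.

    Parameters
    ----------
    theta : array_like
        Deflection angle in radians, 0 <= theta <= pi.
    g : float
        Anisotropy factor, -1 < g < 1.  g = 0 is isotropic scattering.
    """
    _check_g(g)
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("theta must lie in [0, pi]")
    denom = (1.0 + g * g - 2.0 * g * np.cos(theta)) ** 1.5
    return (1.0 - g * g) / (4.0 * np.pi * denom)


def sample_hg_cosine(g, u):
    """Inverse-CDF sample of the HG deflection cosine.

    For g = 0 the cosine is uniform on [-1, 1]; otherwise

        cos(theta) = (1 + g^2 - ((1 - g^2)/(1 - g + 2 g u))^2) / (2 g).

    Deterministic in (g, u); the mean over u ~ U(0,1) equals g.

    Parameters
    ----------
    g : float
        Anisotropy factor, -1 < g < 1.
    u : array_like
        Uniform variate(s) in the open interval (0, 1).
    """
    _check_g(g)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(cos_t, -1.0, 1.0)


def reduced_scattering(mu_s, g):
    """Reduced scattering coefficient mu_s' = mu_s (1 - g), mm^-1."""
    _check_g(g)
    mu_s = np.asarray(mu_s, dtype=float)
    if np.any(mu_s < 0):
        raise ValueError("mu_s must be >= 0")
    out = mu_s * (1.0 - g)
    return float(out) if out.ndim == 0 else out


def fresnel_unpolarized(n_in: float, n_out: float, cos_incident: float) -> float:
    """Unpolarized Fresnel power reflectance at a planar dielectric interface.

    Average of the s- and p-polarized Fresnel reflectances for a ray in the
    medium of index ``n_in`` hitting the interface to ``n_out`` with
    incidence cosine ``cos_incident``.  Beyond the critical angle
    (n_in > n_out) the reflectance is 1 (total internal reflection).
    """
    if n_in < 1.0 or n_out < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_incident <= 1.0:
        raise ValueError(f"cos_incident must lie in [0, 1], got {cos_incident}")
    if n_in == n_out:
        return 0.0
    ci = cos_incident
    sin_i2 = 1.0 - ci * ci
    # Snell: n_in sin_i = n_out sin_t
    sin_t2 = (n_in / n_out) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - sin_t2)
    rs = (n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)
    rp = (n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)
    return float(0.5 * (rs * rs + rp * rp))
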