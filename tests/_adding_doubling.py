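"""Independent adding-doubling solver for azimuthally averaged slab
radiative transfer, used as an oracle against the Monte Carlo forward model.

Implements van de Hulst doubling: Gauss-Legendre discrete ordinates on
(0, 1) plus a zero-weight collimated node, a Henyey-Greenstein
redistribution matrix from the Legendre addition theorem (renormalized for
discrete energy conservation), a single-scattering thin-layer start, and
repeated doubling to the target optical depth.  Matched boundaries (no
Fresnel layers).  Deliberately shares no code with the package's transport
kernel.
"""

import numpy as np


def doubling_rt(
    mu_a: float,
    mu_s: float,
    g: float,
    thickness: float,
    n_quad: int = 64,
    n_legendre: int = 256,
) -> tuple[float, float]:
    """Total (R, T) of a bare slab under collimated normal incidence."""
    mu, w = np.polynomial.legendre.leggauss(n_quad)
    mu = 0.5 * (mu + 1.0)
    w = 0.5 * w
    mu = np.append(mu, 1.0)  # collimated beam node
    w = np.append(w, 0.0)
    n = mu.size
    mu_t = mu_a + mu_s
    if mu_t == 0.0:
        return 0.0, 1.0
    albedo = mu_s / mu_t
    tau = mu_t * thickness

    k = np.arange(n_legendre + 1)
    sigma = (2 * k + 1) * g**k
    legv = np.polynomial.legendre.legvander(mu, n_legendre)
    h_same = (legv * sigma) @ legv.T
    h_opp = (legv * (sigma * (-1.0) ** k)) @ legv.T
    norm = 0.5 * (w @ h_same + w @ h_opp)
    h_same = h_same / norm
    h_opp = h_opp / norm

    n_doubling = max(1, int(np.ceil(np.log2(tau / 1e-7))))
    d = tau / 2**n_doubling
    t = np.diag(np.exp(-d / mu)) + albedo * (d / mu)[None, :] * 0.5 * w[:, None] * h_same
    r = albedo * (d / mu)[None, :] * 0.5 * w[:, None] * h_opp
    eye = np.eye(n)
    for _ in range(n_doubling):
        inv = np.linalg.solve(eye - r @ r, eye)
        t, r = t @ inv @ t, r + t @ inv @ (r @ t)
    return float(r[:, -1].sum()), float(t[:, -1].sum())


def h_function_reflectance(albedo: float, n_grid: int = 1001, n_iter: int = 200) -> float:
    """Semi-infinite isotropic-scattering reflectance at normal incidence,
    via fixed-point iteration of the Chandrasekhar H-function equation."""
    x = np.linspace(1e-6, 1.0, n_grid)
    h = np.ones_like(x)
    for _ in range(n_iter):
        integral = np.trapezoid(
            (x[None, :] * h[None, :]) / (x[:, None] + x[None, :]), x, axis=1
        )
        h = 1.0 / (np.sqrt(1.0 - albedo) + 0.5 * albedo * integral)
    return float(1.0 - np.sqrt(1.0 - albedo) * h[-1])
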