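"""Point inversion of a measured (R, T) pair on a lookup table, and the
simplified substitution calibration for raw detector counts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .lut import LookupTable

__all__ = ["InversionResult", "invert_rt", "calibrate_substitution"]

SIGMA_FLOOR = 1e-4
_BOUNDARY_TOL = 1e-6  # in internal (log) grid units


@dataclass(frozen=True)
class InversionResult:
    """Estimated optical properties for one (R, T) pair."""

    mu_a_hat: float
    mu_s_prime_hat: float
    residual: float
    converged: bool
    on_boundary: bool
    se_mu_a: float = float("nan")
    se_mu_s_prime: float = float("nan")


def invert_rt(R_meas: float, T_meas: float, lut: LookupTable) -> InversionResult:
    """Find the (mu_a, mu_s') whose forward (R, T) best matches the pair.

    Minimizes ((R - R_meas)/sigma_R)^2 + ((T - T_meas)/sigma_T)^2 over the
    bicubic-interpolated surfaces, starting Nelder-Mead from the best grid
    node.  sigma are the Monte Carlo standard errors of the table build,
    floored at 1e-4.  ``on_boundary`` is set when the optimum touches the
    grid hull; ties in the node search break toward smaller mu_a.
    """
    if not (np.isfinite(R_meas) and np.isfinite(T_meas)):
        raise ValueError("R_meas and T_meas must be finite")
    if R_meas < 0 or T_meas < 0 or R_meas > 1 or T_meas > 1:
        raise ValueError("R_meas and T_meas must lie in [0, 1]")
    if R_meas + T_meas > 1:
        warnings.warn(
            f"R + T = {R_meas + T_meas:.4f} > 1 is unphysical; attempting inversion",
            stacklevel=2,
        )

    spl_r, spl_t = lut.splines()
    xa_grid = np.log(lut.mu_a_grid) if lut.mu_a_grid[0] > 0 else lut.mu_a_grid
    xs_grid = (
        np.log(lut.mu_s_prime_grid)
        if lut.mu_s_prime_grid[0] > 0
        else lut.mu_s_prime_grid
    )
    lo = np.array([xa_grid[0], xs_grid[0]])
    hi = np.array([xa_grid[-1], xs_grid[-1]])
    span = hi - lo

    sig_r = np.maximum(lut.se_R, SIGMA_FLOOR)
    sig_t = np.maximum(lut.se_T, SIGMA_FLOOR)

    # node search (tie-break toward smaller mu_a: argmin returns the first
    # minimum and mu_a is the slow axis in C order)
    node_obj = ((lut.R - R_meas) / sig_r) ** 2 + ((lut.T - T_meas) / sig_t) ** 2
    i0, j0 = np.unravel_index(np.argmin(node_obj), node_obj.shape)
    s_r = float(sig_r[i0, j0])
    s_t = float(sig_t[i0, j0])

    def objective(p: np.ndarray) -> float:
        q = np.clip(p, lo, hi)
        r = float(spl_r.ev(q[0], q[1]))
        t = float(spl_t.ev(q[0], q[1]))
        val = ((r - R_meas) / s_r) ** 2 + ((t - T_meas) / s_t) ** 2
        # keep Nelder-Mead inside the hull with a smooth exterior penalty
        overshoot = np.sum(np.maximum(p - hi, 0.0) + np.maximum(lo - p, 0.0))
        return val * (1.0 + overshoot) + 1e6 * overshoot**2

    x0 = np.array([xa_grid[i0], xs_grid[j0]])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    p = np.clip(res.x, lo, hi)
    on_boundary = bool(np.any(p - lo < _BOUNDARY_TOL * span) or np.any(hi - p < _BOUNDARY_TOL * span))
    mu_a_hat, mu_s_prime_hat = lut.from_internal(p[0], p[1])

    # delta-method standard errors from the local surface Jacobian
    se_a = se_s = float("nan")
    try:
        dr_da = float(spl_r.ev(p[0], p[1], dx=1))
        dr_ds = float(spl_r.ev(p[0], p[1], dy=1))
        dt_da = float(spl_t.ev(p[0], p[1], dx=1))
        dt_ds = float(spl_t.ev(p[0], p[1], dy=1))
        jac = np.array([[dr_da, dr_ds], [dt_da, dt_ds]])
        jinv = np.linalg.inv(jac)
        cov_meas = np.diag([s_r**2, s_t**2])
        cov = jinv @ cov_meas @ jinv.T
        # internal axes are logarithmic where the grid is positive
        scale_a = mu_a_hat if lut.mu_a_grid[0] > 0 else 1.0
        scale_s = mu_s_prime_hat if lut.mu_s_prime_grid[0] > 0 else 1.0
        se_a = float(np.sqrt(max(cov[0, 0], 0.0))) * scale_a
        se_s = float(np.sqrt(max(cov[1, 1], 0.0))) * scale_s
    except np.linalg.LinAlgError:
        pass

    return InversionResult(
        mu_a_hat=float(mu_a_hat),
        mu_s_prime_hat=float(mu_s_prime_hat),
        residual=float(max(res.fun, 0.0)),
        converged=bool(res.success),
        on_boundary=on_boundary,
        se_mu_a=se_a,
        se_mu_s_prime=se_s,
    )


def calibrate_substitution(
    raw_sample: float, raw_reference: float, rho_reference: float
) -> tuple[float, bool]:
    """Substitution calibration of a raw count against a reference standard.

    Returns ``rho_reference * raw_sample / raw_reference`` together with a
    clip flag.  A sample cannot reflect more than the reference standard of
    known reflectivity, so the value is clipped to [0, rho_reference].
    """
    if raw_reference <= 0:
        raise ValueError("raw_reference must be > 0")
    if not 0.0 < rho_reference <= 1.0:
        raise ValueError("rho_reference must lie in (0, 1]")
    value = rho_reference * raw_sample / raw_reference
    clipped = value < 0.0 or value > rho_reference
    return float(np.clip(value, 0.0, rho_reference)), clipped
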