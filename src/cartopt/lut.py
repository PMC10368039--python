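"""Forward-model lookup tables over a (mu_a, mu_s') grid.

A :class:`LookupTable` stores the simulated diffuse reflectance and total
transmittance surfaces for one fixed geometry, anisotropy factor and sample
index.  Nodes are simulated with common random numbers (one shared seed), so
tables that differ only in g, n or geometry are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .montecarlo import GapMedium, SampleConstruct, simulate_rt
from .spectra import OpticalProperties

__all__ = ["LookupTable", "build_lut", "save_lut", "load_lut"]


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 4:
        raise ValueError(f"{name} must be 1-D with >= 4 nodes")
    if np.any(grid < 0):
        raise ValueError(f"{name} must be nonnegative")
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return grid


@dataclass(frozen=True)
class LookupTable:
    """R/T surfaces over a strictly increasing (mu_a, mu_s') grid."""

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    R: np.ndarray  # shape (n_mu_a, n_mu_s_prime)
    T: np.ndarray
    se_R: np.ndarray
    se_T: np.ndarray
    g: float
    n_sample: float
    construct: SampleConstruct
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        ga = _check_grid(self.mu_a_grid, "mu_a_grid")
        gs = _check_grid(self.mu_s_prime_grid, "mu_s_prime_grid")
        object.__setattr__(self, "mu_a_grid", ga)
        object.__setattr__(self, "mu_s_prime_grid", gs)
        shape = (ga.size, gs.size)
        for name in ("R", "T", "se_R", "se_T"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")
            if name in ("R", "T") and (
                not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1
            ):
                raise ValueError(f"{name} surface must be finite and within [0, 1]")
            object.__setattr__(self, name, arr)

    # --- interpolation -----------------------------------------------------

    def _axes(self) -> tuple[np.ndarray, np.ndarray, bool, bool]:
        log_a = self.mu_a_grid[0] > 0
        log_s = self.mu_s_prime_grid[0] > 0
        xa = np.log(self.mu_a_grid) if log_a else self.mu_a_grid
        xs = np.log(self.mu_s_prime_grid) if log_s else self.mu_s_prime_grid
        return xa, xs, log_a, log_s

    def splines(self):
        """Bicubic splines of R and T on (log-)parameter axes, cached."""
        cached = getattr(self, "_splines", None)
        if cached is None:
            xa, xs, _, _ = self._axes()
            kx = min(3, xa.size - 1)
            ky = min(3, xs.size - 1)
            cached = (
                RectBivariateSpline(xa, xs, self.R, kx=kx, ky=ky),
                RectBivariateSpline(xa, xs, self.T, kx=kx, ky=ky),
            )
            object.__setattr__(self, "_splines", cached)
        return cached

    def to_internal(self, mu_a: float, mu_s_prime: float) -> tuple[float, float]:
        _, _, log_a, log_s = self._axes()
        return (
            np.log(mu_a) if log_a else mu_a,
            np.log(mu_s_prime) if log_s else mu_s_prime,
        )

    def from_internal(self, xa: float, xs: float) -> tuple[float, float]:
        _, _, log_a, log_s = self._axes()
        return (np.exp(xa) if log_a else xa, np.exp(xs) if log_s else xs)

    def predict(self, mu_a, mu_s_prime) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (R, T) at scalar or array (mu_a, mu_s')."""
        spl_r, spl_t = self.splines()
        xa, xs = self.to_internal(np.asarray(mu_a, float), np.asarray(mu_s_prime, float))
        return spl_r.ev(xa, xs), spl_t.ev(xa, xs)

    def node_sigma(self, mu_a: float, mu_s_prime: float, floor: float = 1e-4) -> tuple[float, float]:
        """MC standard errors of the nearest node, floored."""
        ia = int(np.argmin(np.abs(self.mu_a_grid - mu_a)))
        js = int(np.argmin(np.abs(self.mu_s_prime_grid - mu_s_prime)))
        return (max(float(self.se_R[ia, js]), floor), max(float(self.se_T[ia, js]), floor))


def build_lut(
    mu_a_grid,
    mu_s_prime_grid,
    construct: SampleConstruct,
    g: float,
    n_sample: float,
    n_photons: int,
    seed: int,
) -> LookupTable:
    """Simulate every grid node with :func:`simulate_rt`.

    All nodes share the same seed (common random numbers), so surfaces built
    for different g / n / geometry differ only through the physics, not the
    random stream.  mu_s is derived from the node's mu_s' as mu_s'/(1-g).
    """
    ga = _check_grid(np.asarray(mu_a_grid, float), "mu_a_grid")
    gs = _check_grid(np.asarray(mu_s_prime_grid, float), "mu_s_prime_grid")
    shape = (ga.size, gs.size)
    R = np.empty(shape)
    T = np.empty(shape)
    se_R = np.empty(shape)
    se_T = np.empty(shape)
    for i, mu_a in enumerate(ga):
        for j, msp in enumerate(gs):
            props = OpticalProperties.from_reduced(mu_a, msp, g, n_sample)
            res = simulate_rt(props, construct, n_photons, seed)
            R[i, j] = res.R_diffuse
            T[i, j] = res.T_total
            se_R[i, j] = res.se_R
            se_T[i, j] = res.se_T
    return LookupTable(
        mu_a_grid=ga,
        mu_s_prime_grid=gs,
        R=R,
        T=T,
        se_R=se_R,
        se_T=se_T,
        g=float(g),
        n_sample=float(n_sample),
        construct=construct,
        n_photons=int(n_photons),
        seed=int(seed),
    )


# --- persistence (HDF5) ----------------------------------------------------


def save_lut(lut: LookupTable, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("mu_a_grid", "mu_s_prime_grid", "R", "T", "se_R", "se_T"):
            f.create_dataset(name, data=getattr(lut, name))
        f.attrs["g"] = lut.g
        f.attrs["n_sample"] = lut.n_sample
        f.attrs["n_photons"] = lut.n_photons
        f.attrs["seed"] = lut.seed
        c = asdict(lut.construct)
        c["gap_medium"] = asdict(lut.construct.gap_medium)
        f.attrs["construct"] = json.dumps(c)


def load_lut(path) -> LookupTable:
    import h5py

    with h5py.File(path, "r") as f:
        c = json.loads(f.attrs["construct"])
        c["gap_medium"] = GapMedium(**c["gap_medium"])
        return LookupTable(
            mu_a_grid=f["mu_a_grid"][:],
            mu_s_prime_grid=f["mu_s_prime_grid"][:],
            R=f["R"][:],
            T=f["T"][:],
            se_R=f["se_R"][:],
            se_T=f["se_T"][:],
            g=float(f.attrs["g"]),
            n_sample=float(f.attrs["n_sample"]),
            construct=SampleConstruct(**c),
            n_photons=int(f.attrs["n_photons"]),
            seed=int(f.attrs["seed"]),
        )
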