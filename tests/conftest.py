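import numpy as np
import pytest

from cartopt import OpticalProperties, SampleConstruct, build_lut
from cartopt.lut import LookupTable
from cartopt.montecarlo import GapMedium


@pytest.fixture(scope="session")
def default_construct():
    return SampleConstruct()


@pytest.fixture(scope="session")
def matched_slab():
    """Wide, index-matched bare-slab construct for oracle comparisons."""
    return SampleConstruct(
        sample_radius=60.0,
        holder_radius=62.0,
        sample_thickness=20.0,
        window_n=1.0,
        beam_radius=0.5,
        gap_medium=GapMedium("air", 0.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_lut(default_construct):
    """Small Monte Carlo lookup table around cartilage-like properties."""
    return build_lut(
        np.geomspace(5e-3, 0.5, 8),
        np.geomspace(0.4, 3.0, 7),
        default_construct,
        g=0.9,
        n_sample=1.358,
        n_photons=15_000,
        seed=11,
    )


def analytic_surfaces(mu_a_grid, mu_s_grid):
    """Smooth invertible closed-form stand-in for (R, T) surfaces."""
    a, s = np.meshgrid(mu_a_grid, mu_s_grid, indexing="ij")
    R = 0.6 * (s / (1.0 + s)) * np.exp(-a)
    T = np.exp(-3.0 * a) / (1.0 + 0.5 * s)
    return R, T


@pytest.fixture(scope="session")
def analytic_lut(default_construct):
    """Noise-free analytic lookup table (closed-form surfaces, zero SE)."""
    ga = np.geomspace(1e-3, 1.0, 25)
    gs = np.geomspace(0.1, 5.0, 25)
    R, T = analytic_surfaces(ga, gs)
    zero = np.zeros_like(R)
    return LookupTable(
        mu_a_grid=ga,
        mu_s_prime_grid=gs,
        R=R,
        T=T,
        se_R=zero,
        se_T=zero,
        g=0.9,
        n_sample=1.358,
        construct=default_construct,
        n_photons=0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
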