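import numpy as np
import pytest

from spherowave import (
    ModelParams,
    NoiseSpec,
    RadialGrid,
    generate_density_series,
    make_initial_profile,
    simulate,
)


@pytest.fixture(scope="session")
def coarse_grid():
    """Small grid for cheap solver tests."""
    return RadialGrid.uniform(L=5.0, n=64)


@pytest.fixture(scope="session")
def fit_grid():
    """Grid used for fitting tests (data grid == solver grid)."""
    return RadialGrid.uniform(L=5.0, n=100)


@pytest.fixture(scope="session")
def rd_truth():
    return ModelParams("RD", D1=0.05, rho1=5.0, K1=0.4)


@pytest.fixture(scope="session")
def rd_series_noiseless(rd_truth, fit_grid):
    """Noiseless RD data: 8 time points over one week."""
    obs, truth = generate_density_series(
        rd_truth, np.linspace(0, 1, 8), fit_grid, noise=NoiseSpec(kind="none")
    )
    return obs, truth


@pytest.fixture(scope="session")
def two_pop_params():
    """Strongly separated two-population scenario (fast second population)."""
    return ModelParams(
        "RD_ARD", D1=0.007, rho1=2.5, K1=0.65, D2=0.07, rho2=1.5, K2=0.4,
        A2=0.4, alpha=0.5,
    )


@pytest.fixture(scope="session")
def translating_front_series():
    """Exact rigid translation at 0.5 mm/week (whole-node shifts)."""
    grid = RadialGrid.uniform(L=5.0, n=201)  # dr = 0.025 mm
    times = np.arange(0.0, 1.01, 0.25)  # shift per step = 0.125 mm = 5 nodes
    profile = lambda r: 0.5 / (1.0 + np.exp((r - 1.0) / 0.1))
    u = np.vstack([profile(grid.r - 0.5 * t) for t in times])
    from spherowave import RadialDensitySeries

    return RadialDensitySeries(times, grid, u)
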