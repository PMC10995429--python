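"""Shared fixtures: the expensive production-resolution runs are computed
once per session and reused by the regime, velocity and consistency tests."""

import numpy as np
import pytest

import flowtaxis as ft

#: output times for the production runs: dense enough to confirm the sign
#: of Ndiff throughout, and containing the t = 100, 500, 1000 snapshots
PRODUCTION_TIMES = [0.0] + [float(t) for t in range(50, 1001, 50)]


@pytest.fixture(scope="session")
def run_phibar02():
    """Production run at phi_bar = 0.2, Da = 0.5, T = 10 (chemotaxis-dominated)."""
    params = ft.NondimParams(phi_bar=0.2, Da=0.5, T=10.0)
    grid = ft.Grid1D(X=30.0, N=1201)
    return ft.run(params, grid=grid, dt=0.01, output_times=PRODUCTION_TIMES)


@pytest.fixture(scope="session")
def run_phibar04():
    """Run at phi_bar = 0.4, Da = 0.5, T = 10 (early tensotaxis dominance)."""
    params = ft.NondimParams(phi_bar=0.4, Da=0.5, T=10.0)
    grid = ft.Grid1D(X=30.0, N=601)
    return ft.run(params, grid=grid, dt=0.02, output_times=[0.0, 100.0, 500.0, 1000.0])


@pytest.fixture(scope="session")
def small_grid():
    """Cheap grid for unit tests of solver mechanics."""
    return ft.Grid1D(X=15.0, N=301)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
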