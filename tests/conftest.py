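import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from littherm.phantom import (
    ApplicatorGeometry,
    CohortConfig,
    LaserRegimen,
    SimulationGrid,
    TissueParams,
    generate_case,
    solve_pennes,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def standard_series():
    """Standard one-fiber regimen on the default grid (deterministic)."""
    return solve_pennes(TissueParams(), [ApplicatorGeometry()], LaserRegimen(), dt=2.0)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def standard_case(default_config):
    """One fully encoded synthetic case (tumor, both arms, truth)."""
    return generate_case(default_config, "case-std", seed=42)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast solver tests; monitored slices at indices 1/4/7."""
    return SimulationGrid(nx=64, ny=64, nz=9)


@pytest.fixture(scope="session")
def small_config(small_grid):
    return CohortConfig(grid=small_grid, store_interval=60.0)
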