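import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dosefield as dfd
from dosefield.volume import GridSpec, Mask, make_sphere_mask

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231026)


@pytest.fixture
def small_grid():
    """6x6x6 grid at 4 mm, centered."""
    return GridSpec.isotropic((6, 6, 6), 4.0)


@pytest.fixture
def sim_grid():
    return GridSpec.isotropic((16, 16, 16), 4.0)


@pytest.fixture
def sim_mask(sim_grid):
    return make_sphere_mask(sim_grid, (0.0, 0.0, 0.0), 28.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3+3 subjects, default plant, shared across read-only tests."""
    cfg = dfd.CohortConfig(n_active=3, n_sham=3)
    return dfd.generate_cohort(cfg, 11)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return dfd.CohortConfig(
        n_active=2, n_sham=2,
        noise_sd_bold=0.0, motion_walk_sd=0.0, motion_spike_prob=0.0,
        plant=dfd.PlantSpec(level="none"),
        ef=dfd.EFFieldParams(amp_cv=0.0, jitter_mm=0.0),
    )


def full_mask(grid):
    return Mask(grid, np.ones(grid.dims, dtype=bool))
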