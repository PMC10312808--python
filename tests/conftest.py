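import numpy as np
import pytest

from normgain import model as nm
from normgain.cohort import CohortConfig, preset_config, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return nm.DEFAULT_PARAMS


@pytest.fixture
def tiny_grid():
    """9-sample grid for nested-loop oracle comparisons."""
    positions = 1.0 * np.arange(-4, 5, dtype=float)
    return nm.SpatialGrid(positions, 1.0, n_directions=2)


@pytest.fixture
def small_grid(params):
    return nm.SpatialGrid.make(40.0, 0.5, guard_margin=6.0)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared across tests."""
    cfg = CohortConfig(seed=424242, n_subjects=14)
    return simulate_study(cfg, "exp1")


@pytest.fixture(scope="session")
def exp1_report(tmp_path_factory):
    from normgain.pipeline import RunConfig, run_exp1

    out = tmp_path_factory.mktemp("exp1")
    cfg = RunConfig(
        seed=31, simulate={"preset": "exp1", "n": 32}, outdir=str(out)
    )
    return cfg, run_exp1(cfg)
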