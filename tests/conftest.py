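import numpy as np
import pytest

from dsmap.grid_symmetry import MillerGrid, UnitCell
from dsmap.scaling import RefinementConfig, refine
from dsmap.simulator import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def insulin_like_grid() -> MillerGrid:
    """Subdivision-3 grid for an I-centered cubic cell, Laue group m-3̄."""
    return MillerGrid.from_preset(UnitCell.cubic(79.48), 3, "I", "m-3")


@pytest.fixture(scope="session")
def small_experiment():
    """A quick synthetic experiment (all four artifacts active)."""
    cfg = SimulationConfig(seed=11, obs_per_sweep=6000, n_voxels=600)
    obs, truth = simulate_experiment(cfg)
    return cfg, obs, truth


@pytest.fixture(scope="session")
def default_experiment():
    """The full-size study conditions: 2 sweeps x 50k observations."""
    cfg = SimulationConfig(seed=1)
    obs, truth = simulate_experiment(cfg)
    return cfg, obs, truth


@pytest.fixture(scope="session")
def refined_experiment(default_experiment):
    """Full four-term refinement of the default experiment."""
    cfg, obs, truth = default_experiment
    rc = RefinementConfig.full_model(d_nx=31, d_ny=31)
    model, merged, diag = refine(obs, rc)
    return cfg, obs, truth, model, merged, diag
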