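import numpy as np
import pytest

from reeftrack.config import PipelineConfig
from reeftrack.pipeline import run_pipeline
from reeftrack.prep import DayWindow, RegularTrajectory
from reeftrack.simulate import SimulationConfig, build_triangular_array, simulate_trajectory


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study conditions.

    Shared across tests that exercise end-to-end products (localized fixes,
    home ranges, behavioral classes); seeded so every test sees the same
    realization.
    """
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def day_traj():
    """One simulated fish at 1-min resolution, repackaged per day."""
    cfg = SimulationConfig(n_days=14, rng_seed=11)
    traj = simulate_trajectory(cfg)
    sr, ss = cfg.day_window
    days = {}
    for day in range(cfg.n_days):
        i0 = day * 1440 + sr
        n = ss - sr
        days[day] = RegularTrajectory(
            "F1",
            day,
            np.arange(float(sr), float(ss) + 1)[:n],
            traj.positions[i0 : i0 + n, :2],
            np.full(n, "observed", dtype=object),
        )
    return cfg, traj, days


@pytest.fixture()
def small_array():
    return build_triangular_array((0.0, 0.0, 200.0, 100.0), spacing=60.0, timing_noise_sd=0.0)


@pytest.fixture()
def noon_window():
    return DayWindow(0, 360.0, 1080.0)
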