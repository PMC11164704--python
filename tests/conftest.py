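import numpy as np
import pandas as pd
import pytest

from thermosoar import ThermalParams, WindConfig, vulture_params


@pytest.fixture(scope="session")
def glider():
    return vulture_params()


@pytest.fixture(scope="session")
def thermal():
    return ThermalParams()  # w* = 5 m/s, z* = 2000 m


@pytest.fixture
def circle_track():
    """Analytic circle factory: radius R, speed V, optional drift u."""

    def make(R=30.0, V=15.0, u=0.0, duration=200.0, z0=500.0, sink=0.0,
             ccw=True, phase=0.0):
        t = np.arange(0.0, duration + 0.5, 1.0)
        om = (V / R) * (1.0 if ccw else -1.0)
        return pd.DataFrame(
            {
                "t": t,
                "x": R * np.cos(om * t + phase) + u * t,
                "y": R * np.sin(om * t + phase),
                "z": z0 - sink * t,
            }
        )

    return make


@pytest.fixture(scope="session")
def circler_fixtures():
    """Simulated constant-control circling tracks with known ground truth.

    20 seeded trajectories with bank angles in [20, 45] deg and winds in
    [0, 5] m/s — the validation set for the kinematic estimators.
    """
    from thermosoar.io_cli import scripted_circler

    rng = np.random.default_rng(1)
    out = []
    for seed in range(1, 21):
        sigma = float(rng.uniform(20.0, 45.0))
        u = float(rng.uniform(0.0, 5.0))
        traj = scripted_circler(sigma, 8.0, WindConfig(u=u), 200.0, seed)
        out.append((sigma, u, traj))
    return out
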