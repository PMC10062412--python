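import numpy as np
import pytest

from virodyn import (NondimParams, SimulationSettings, Trajectory,
                     baseline_params)


@pytest.fixture(scope="session")
def baseline() -> NondimParams:
    """The packaged worked-example parameter set (symmetric immune case)."""
    return baseline_params()


@pytest.fixture(scope="session")
def case1_params() -> NondimParams:
    """Asymmetric clearance with the innate compartment advantaged
    (h1 < h2) and strong enough clearance that lambda1 < 0."""
    return NondimParams(r=0.36, a=5.0, l1=0.48, l2=0.48, e1=10.0, e2=10.0,
                        d1=0.7, d2=0.9, tau1=0.2, tau2=0.2)


def make_trajectory(states2d, dt: float = 0.1) -> Trajectory:
    """Wrap a bare (n, 2) or (n, 4) sample cloud as a Trajectory for the
    analysis routines (zero Brownian drivers, no dynamics implied)."""
    states2d = np.asarray(states2d, dtype=float)
    n = len(states2d)
    states = np.zeros((n, 4))
    states[:, :states2d.shape[1]] = states2d
    t = np.arange(n) * dt
    settings = SimulationSettings(t_end=max(t[-1], dt), dt=dt, save_stride=1)
    return Trajectory(times=t, states=states, W=np.zeros((n, 2)),
                      params=None, settings=settings, init=states[0])
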