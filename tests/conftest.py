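import numpy as np
import pytest

from calipath.trajectory import BinningSpec, DiscreteTrajectory, PathEnsemble


@pytest.fixture
def binning32():
    return BinningSpec(32, -15.0, 15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_traj(states, binning=None, dt=1.0):
    return DiscreteTrajectory(states=np.asarray(states), dt=dt, binning=binning)


def make_ensemble(rows, binning=None, dt=1.0, weights=None):
    return PathEnsemble(
        trajectories=[make_traj(r, binning=binning, dt=dt) for r in rows],
        weights=weights,
    )
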