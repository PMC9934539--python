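import numpy as np
import pandas as pd
import pytest

from rankdecon import RunConfig, SimConfig, simulate_discrete, simulate_trajectory
from rankdecon.core import train_model

# Small but non-trivial instances shared across tests.  High DE keeps the
# deconvolution signal strong at this scale.

SMALL_DISCRETE = SimConfig(
    n_genes=500, n_cells=300, group_probs=(1 / 3, 1 / 3, 1 / 3),
    de_prob=0.1, de_fac_loc=0.6, seed=11,
)

SMALL_TRAJECTORY = SimConfig(
    n_genes=500, n_cells=400, group_probs=(1 / 3, 1 / 3, 1 / 3),
    de_prob=0.1, de_fac_loc=0.6, topology=(0, 1, 1), n_steps=12, seed=13,
)

SMALL_RUN = RunConfig(n_var_genes=200, n_dims=5, n_train=400, seed=7)


@pytest.fixture(scope="session")
def small_discrete():
    return simulate_discrete(SMALL_DISCRETE)


@pytest.fixture(scope="session")
def small_trajectory():
    return simulate_trajectory(SMALL_TRAJECTORY)


@pytest.fixture(scope="session")
def small_model(small_discrete):
    return train_model(small_discrete.counts, config=SMALL_RUN)


@pytest.fixture(scope="session")
def small_traj_model(small_trajectory):
    return train_model(small_trajectory.counts, config=SMALL_RUN)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
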