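import numpy as np
import pytest

from tcox import SimulationConfig, SurvivalDataset, simulate_dataset


def make_survival(n=60, p=4, beta=None, censor_frac=0.3, rate=0.05, seed=0):
    """Small right-censored dataset from a proportional-hazards model."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    t = -np.log(rng.uniform(size=n)) / (rate * np.exp(X @ beta))
    status = (rng.uniform(size=n) >= censor_frac).astype(int)
    if status.sum() == 0:
        status[0] = 1
    return SurvivalDataset(X, t, status, [f"g{j}" for j in range(p)])


@pytest.fixture
def small_survival():
    return make_survival(n=60, p=4, beta=[0.8, -0.5, 0, 0], seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study reused by several evaluation tests."""
    cfg = SimulationConfig(n_tumor=150, n_normal=150, p=20, block_size=5,
                           n_rewired=4, seed=11)
    return simulate_dataset(cfg)
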