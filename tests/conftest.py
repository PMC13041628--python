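import numpy as np
import pytest

import campaignsim as cs
from campaignsim.dynamics import ArrayPopulation


def make_toy_population(n: int, seed: int = 0, b_annual: float = 0.5,
                        a_tv: float | None = None) -> ArrayPopulation:
    """Small array-backed population: one-hot posteriors cycling through the
    6 classes, moderate channel use, common baseline propensity."""
    rng = np.random.default_rng(seed)
    modal = np.arange(n) % 6 + 1
    post = np.zeros((n, 6))
    post[np.arange(n), modal - 1] = 1.0
    a = rng.uniform(0.2, 0.9, size=(n, 3))
    if a_tv is not None:
        a[:, 0] = a_tv
    b = np.full(n, cs.annual_to_step_hazard(b_annual, 12))
    deg = rng.integers(2, 11, n)
    return ArrayPopulation(posterior=post, modal_class=modal, a=a, b_step=b,
                           degree_targets=deg)


@pytest.fixture(scope="session")
def pop_vacc() -> cs.Population:
    return cs.default_population("vaccination", seed=11)


@pytest.fixture(scope="session")
def pop_scr() -> cs.Population:
    return cs.default_population("screening", seed=11)


@pytest.fixture(scope="session")
def toy_pop() -> ArrayPopulation:
    return make_toy_population(300, seed=3)
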