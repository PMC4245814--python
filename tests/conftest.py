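import numpy as np
import pytest

from invasionabc.abcfit import PriorSpec, to_sim_params
from invasionabc.coalsim import default_sample_config, simulate_dataset
from invasionabc.synthdata import make_toy_fixture
from invasionabc.validate import SimulationStudy


class ToyPrior:
    """Uniform prior over a single location parameter (test toys)."""

    def __init__(self, lo=-3.0, hi=3.0):
        self.lo, self.hi = lo, hi
        self.names = ["theta"]

    def support(self, name):
        return (self.lo, self.hi)

    def sample(self, rng):
        return {"theta": float(rng.uniform(self.lo, self.hi))}

    def vector(self, draw):
        return np.array([draw["theta"]])


def gaussian_toy_study(offsets, sd=1.0, n_noise=0):
    """Conjugate Gaussian toy: models differ by a location offset of the
    first statistic, which is theta + offset + noise."""
    prior = ToyPrior()

    def simulate(model, draw, rng):
        s = draw["theta"] + offsets[model] + sd * rng.normal()
        noise = rng.normal(size=n_noise)
        return np.concatenate([[s], noise])

    names = ["s"] + [f"noise{i}" for i in range(n_noise)]
    return SimulationStudy(list(offsets), prior, simulate, names)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim_dataset():
    """One simulated five-region dataset with missing data, shared by
    tests that only need a realistic-shaped input."""
    prior = PriorSpec()
    rng = np.random.default_rng(99)
    params = to_sim_params(prior.sample(rng))
    config = default_sample_config()
    return simulate_dataset("M1", params, config, rng, missing_rate=0.214)


@pytest.fixture
def pi_onethird():
    return make_toy_fixture("pi_onethird")


@pytest.fixture
def fst_one():
    return make_toy_fixture("fst_one")
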