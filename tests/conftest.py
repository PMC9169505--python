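import numpy as np
import pytest

from asbtrial.data_model import Dataset, RawTLQSeries, Treatment


@pytest.fixture
def flat_series():
    """A constant mid-scale trajectory under the active control."""
    return RawTLQSeries("s1", 1, Treatment.PEI, [6] * 21)


@pytest.fixture
def toy_series():
    """A hand-checkable trajectory: flat PRE, a 2-point loudness drop
    during ONLINE, partial rebound in POST."""
    raw = [6, 6, 6, 6, 6, 6, 5, 5, 4, 4, 4, 4, 4, 4, 4, 4, 4, 5, 5, 6, 6]
    return RawTLQSeries("s1", 1, Treatment.PEI, raw)


@pytest.fixture
def small_dataset():
    """Six subjects x 3 sessions of simulated crossover data."""
    from asbtrial.simulate import simulate_dataset

    return simulate_dataset(6, seed=42)


@pytest.fixture(scope="session")
def quick_draws():
    """A short but real posterior fit on a small simulated cohort,
    shared across tests that only need plausible draws."""
    from asbtrial import inference, simulate

    dataset = simulate.simulate_dataset(6, seed=7)
    fit = inference.FitConfig(chains=2, iterations=600, burn_in=300,
                              seed=5, store_random_effects=False)
    return inference.fit_mcmc(dataset, inference.ModelConfig(), fit)
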