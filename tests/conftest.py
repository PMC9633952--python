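import numpy as np
import pytest

from eegselect import CriterionConfig, CriterionEvaluator, SimConfig, simulate_mi


@pytest.fixture(scope="session")
def separable_epochs():
    """Strongly separable two-class set: 16 channels, 50 trials/class."""
    return simulate_mi(SimConfig(n_trials=50, seed=1))


@pytest.fixture(scope="session")
def separable_evaluator(separable_epochs):
    return CriterionEvaluator(separable_epochs, CriterionConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
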