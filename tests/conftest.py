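import numpy as np
import pytest

from pairavg import (
    GeneratorConfig,
    constant_coefficient,
    enumerate_conditions,
    generate_dataset,
)


@pytest.fixture(scope="session")
def table4():
    """The canonical 4-category x 2-location condition table (20 conditions)."""
    return enumerate_conditions(4, 2)


@pytest.fixture
def averaging_dataset():
    """Noise-free subject whose pair responses are exact equal averages."""
    config = GeneratorConfig(
        n_units=100,
        n_runs=10,
        noise_sd=0.0,
        combination_rule="weighted_sum",
        coefficient=constant_coefficient(0.5),
        seed=11,
    )
    return generate_dataset(config, 0)


@pytest.fixture
def noisy_averaging_config():
    """Exact-averaging generator with moderate run noise."""
    return GeneratorConfig(
        n_units=100,
        n_runs=10,
        noise_sd=1.0,
        combination_rule="weighted_sum",
        coefficient=constant_coefficient(0.5),
        seed=23,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
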