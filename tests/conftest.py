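import numpy as np
import pytest

from otoraman import SimulationConfig, despike_dataset, generate_dataset
from otoraman.screen import assigned_labels, screen_dataset
from otoraman.synthetic import default_phenotypes


@pytest.fixture(scope="session")
def phenotypes():
    return {m.label: m for m in default_phenotypes()}


@pytest.fixture(scope="session")
def axis():
    return SimulationConfig().axis


@pytest.fixture(scope="session")
def default_dataset():
    """Default-size noisy cohort (8 specimens x 10 sites per class)."""
    return generate_dataset(SimulationConfig(rng_seed=0))


@pytest.fixture(scope="session")
def despiked_dataset(default_dataset):
    ds, _ = despike_dataset(default_dataset)
    return ds


@pytest.fixture(scope="session")
def screen_labels(despiked_dataset):
    return assigned_labels(screen_dataset(despiked_dataset), despiked_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy cohort for fast evaluation tests."""
    return generate_dataset(
        SimulationConfig(n_specimens_per_class=4, n_sites_per_specimen=5, rng_seed=11)
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free cohort: no shot noise, no cosmic spikes."""
    return generate_dataset(
        SimulationConfig(
            n_specimens_per_class=4,
            n_sites_per_specimen=5,
            shot_noise=False,
            spike_rate=0.0,
            rng_seed=5,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
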