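import numpy as np
import pytest

from trflpkit.pipeline import scenario_fragments, scenario_profiles
from trflpkit.simulate import ScenarioConfig, generate_scenario
from trflpkit.trflp import bin_and_standardize


@pytest.fixture
def small_config():
    """Reduced scenario for fast unit tests."""
    return ScenarioConfig(
        otu_pool_size=40,
        n_stations_offpath=0,
        amplicon_length=1100,
        trf_range=(34, 900),
        seed=11,
    )


@pytest.fixture
def noise_free_config(small_config):
    import dataclasses

    return dataclasses.replace(small_config, noise_cv=0.0, succession_rate=4e-4)


@pytest.fixture
def small_scenario(small_config):
    return generate_scenario(small_config)


def fingerprint_scenario(scenario, noise_cv=0.0, seed=0, **bin_kwargs):
    """Run the digest -> profile -> bin chain on a scenario."""
    frags = scenario_fragments(scenario, "GCGC", 3)
    profiles = scenario_profiles(scenario, frags, noise_cv=noise_cv, seed=seed)
    return bin_and_standardize(profiles, **bin_kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
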