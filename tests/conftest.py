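import numpy as np
import pandas as pd
import pytest

from spermatophore.simulate import (
    SimulationConfig,
    default_config,
    make_ground_truth,
    planted_config,
    simulate_proteome,
    write_fixture_bundle,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation config."""
    return planted_config(
        seed=7,
        n_genes=60,
        fold=10.0,
        n_sex_male=5,
        n_sex_female=3,
        n_testes_biased=5,
        n_mag_biased=3,
        n_testes_specific=3,
        n_novel=5,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_proteome(small_config, small_truth):
    return simulate_proteome(small_config, small_truth)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
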