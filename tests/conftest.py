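import numpy as np
import pytest

from dynhub import fixed_fixture, generate_cohort, load_region_table, null_config


@pytest.fixture(scope="session")
def table():
    return load_region_table()


@pytest.fixture(scope="session")
def toy5():
    return fixed_fixture("toy5")


@pytest.fixture(scope="session")
def selections():
    return fixed_fixture("results_selections")


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort (8+8 subjects, 60 volumes) for fast pipeline tests."""
    cfg = null_config(seed=42, n_per_group=8)
    cfg.n_volumes = 60
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20190620)
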