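import numpy as np
import pytest

from reprt import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-CM, 3-family synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_molecules=80,
        n_cms=6,
        n_families=3,
        n_groups=8,
        frac_outgeneral=0.25,
        frac_nonretained=0.10,
        noise_sd=0.03,
        seed=7,
    )
    table, cms, truth = generate_dataset(cfg)
    return cfg, table, cms, truth


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results never depend on
    # which other tests ran first
    return np.random.default_rng(12345)
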