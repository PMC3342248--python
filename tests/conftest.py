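import numpy as np
import pytest

import standforge as sf


@pytest.fixture(scope="session")
def small_stand() -> sf.StandDataset:
    """A modest synthetic stand (160×160 m) shared by read-only tests."""
    cfg = sf.StandConfig(width_m=160.0, height_m=160.0, rng_seed=5, n_transects=24)
    return sf.generate_stand(cfg)


@pytest.fixture(scope="session")
def registry():
    return sf.allometry.load_default_registry()


@pytest.fixture(scope="session")
def densities():
    return sf.allometry.load_default_densities()


@pytest.fixture(scope="session")
def fuel_coefficients():
    return sf.allometry.load_default_fuel_coefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
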