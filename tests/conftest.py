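import numpy as np
import pytest

from ratpheno.core_data import zscore
from ratpheno.synthetic import SyntheticConfig, generate_battery


@pytest.fixture(scope="session")
def default_battery():
    """One default synthetic battery (45 rats, 26 variables) plus ground truth."""
    return generate_battery(SyntheticConfig(), seed=42)


@pytest.fixture(scope="session")
def default_z(default_battery):
    dataset, _ = default_battery
    return zscore(dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
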