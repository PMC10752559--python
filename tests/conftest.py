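import numpy as np
import pytest

from cheatnet.community import generate_community
from cheatnet.fieldsynth import FieldConfig, generate_field_dataset


@pytest.fixture(scope="session")
def community20():
    return generate_community(n_P=20, n_A=20, phi=0.4, seed=42)


@pytest.fixture(scope="session")
def field_dataset():
    """A small synthetic field survey shared across estimator tests."""
    return generate_field_dataset(FieldConfig(n_sites=6), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
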