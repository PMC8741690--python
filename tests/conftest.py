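import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from monodiab.grs import GenotypeMatrix, WeightTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_weights():
    from monodiab.simulate import load_default_weights

    return load_default_weights()


@pytest.fixture()
def toy_weights():
    """Three SNPs with weights 1, 2, 1."""
    return WeightTable(
        ("snpA", "snpB", "snpC"),
        ("1", "2", "3"),
        (100, 200, 300),
        ("A", "C", "G"),
        ("G", "T", "A"),
        np.array([1.0, 2.0, 1.0]),
    )


@pytest.fixture()
def toy_genotypes():
    return GenotypeMatrix(
        ("kid1", "kid2", "kid3"),
        ("snpA", "snpB", "snpC"),
        np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211023)
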