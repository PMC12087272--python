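import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    from rgpri.datasets import packaged_dataset

    return packaged_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def synthetic_molecule():
    """One deterministic synthetic molecule with its energy triple."""
    from rgpri.datasets import SyntheticSpec, generate_synthetic_molecule

    return generate_synthetic_molecule(SyntheticSpec(seed=7))
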