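import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyfusion import experiments
from polyfusion.genome import apply_sv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    return experiments.toy_locus(seed=7)


@pytest.fixture(scope="session")
def complex_sv():
    return experiments.toy_sv("COMPLEX_INV_DEL")


@pytest.fixture(scope="session")
def complex_hap(genome, complex_sv):
    return apply_sv(genome.sequence, complex_sv)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
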