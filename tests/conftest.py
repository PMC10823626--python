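import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    """3 genes / 12 isoforms, lengths 200-1000 (fast, deterministic)."""
    from masiso.reference import make_sirv_like_module
    return make_sirv_like_module(3, 12, 200, 1000, seed=7)


@pytest.fixture(scope="session")
def sirv_reference():
    """Spike-in sized module: 7 genes / 69 isoforms, 160-2,940 bp."""
    from masiso.reference import make_sirv_like_module
    return make_sirv_like_module(7, 69, 160, 2940, seed=1)


@pytest.fixture(scope="session")
def designs():
    from masiso.library_sim import make_array_designs
    return make_array_designs([2, 4], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
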