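import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def group_params():
    from onhmorph.synthetic import load_group_params

    return load_group_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A rendered 5/5/5 cohort shared by read-only tests."""
    from onhmorph.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(groups={"NTG": 5, "CRAO": 5, "healthy": 5})
    return generate_cohort(cfg, seed=11)
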