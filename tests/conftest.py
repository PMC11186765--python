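import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def describe_specs():
    return evb.describe_subcohort2_specs()


@pytest.fixture(scope="session")
def describe_cohort(describe_specs):
    """One seeded discovery-like cohort with confirmed-pathology labels."""
    table = evb.generate_cohort(describe_specs, seed=20240, cohort="DESCRIBE-2")
    return evb.inject_pathology_labels(table, describe_specs, seed=20241)


@pytest.fixture(scope="session")
def sant_pau_cohort():
    specs = evb.sant_pau_specs()
    table = evb.generate_cohort(specs, seed=20242, cohort="SantPau")
    return evb.inject_pathology_labels(table, specs, seed=20243)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
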