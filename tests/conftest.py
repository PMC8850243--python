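import pytest
from hypothesis import HealthCheck, settings

from namtier import load_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ec1():
    return load_fixture("EC1")


@pytest.fixture(scope="session")
def ec2():
    return load_fixture("EC2")


@pytest.fixture(scope="session")
def ec3():
    return load_fixture("EC3")
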