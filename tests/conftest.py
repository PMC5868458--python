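import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg():
    from bbbsim.config import resolve_config

    return resolve_config()


@pytest.fixture(scope="session")
def expression_records():
    from bbbsim.overlay import load_expression_fixture

    return load_expression_fixture()


@pytest.fixture(scope="session")
def records_by_symbol(expression_records):
    return {r.symbol: r for r in expression_records}
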