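import pytest
from hypothesis import HealthCheck, settings

import migraine_cua as m

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def base_config() -> m.ModelConfig:
    """Packaged base case (fresh copy per test)."""
    return m.default_paper_config()


@pytest.fixture(scope="session")
def base_result() -> m.CEAResult:
    """Base-case comparison, computed once per session."""
    return m.run_base_case(m.default_paper_config())
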