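import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "secanalyze",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("secanalyze")


@pytest.fixture(scope="session")
def landscape():
    """One default synthetic enhancer landscape, shared across tests."""
    from secanalyze.simulate import simulate_enhancer_landscape

    return simulate_enhancer_landscape(seed=7)
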