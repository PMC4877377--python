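import pytest
from hypothesis import HealthCheck, settings

from confelem import fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def examples():
    """The shared worked-example registry, keyed by short names."""
    exs = fixtures.worked_examples()
    return {
        "flux_cone": exs[0],
        "quadrant": exs[1],
        "cone2": exs[2],
        "poly3": exs[3],
        "flux_poly": exs[4],
        "knockout": exs[5],
    }


@pytest.fixture(scope="session")
def running_network():
    return fixtures.running_example_network()
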