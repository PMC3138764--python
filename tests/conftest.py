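import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from oboreason.convert import convert
from oboreason.fixtures import WORKED_EXAMPLES, worked_example
from oboreason.reasoner import Reasoner


@pytest.fixture(scope="session")
def bundles():
    """All worked-example bundles, built once."""
    return {name: worked_example(name) for name in WORKED_EXAMPLES}


@pytest.fixture(scope="session")
def reasoner_for():
    cache = {}

    def get(bundle):
        key = id(bundle)
        if key not in cache:
            cache[key] = Reasoner(convert([bundle.document], bundle.config))
        return cache[key]

    return get
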