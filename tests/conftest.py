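import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aesignal import make_figure4_fixture  # noqa: E402


@pytest.fixture()
def figure4():
    """Fresh copy of the worked-example ontology and its code mapping."""
    return make_figure4_fixture()


@pytest.fixture()
def figure4_ontology(figure4):
    return figure4[0]


@pytest.fixture()
def figure4_mapping(figure4):
    return figure4[1]
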