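import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    from ssvep_speller import default_layout

    return default_layout()


@pytest.fixture(scope="session")
def qwerty():
    from ssvep_speller import qwerty_layout

    return qwerty_layout()
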