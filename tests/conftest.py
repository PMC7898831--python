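import pytest
from hypothesis import HealthCheck, settings

from eqshift import ReactionSystem
from eqshift.synthetic import make_reference_spectra

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uridine_system() -> ReactionSystem:
    """The demonstration system: 2 mM uridine, 8 mM phosphate, K = 0.15."""
    return ReactionSystem(N0=2.0, P0=8.0, K=0.15)


@pytest.fixture(scope="session")
def refs():
    """Default synthetic reference spectra (well-conditioned)."""
    return make_reference_spectra()
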