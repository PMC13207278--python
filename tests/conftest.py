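import pytest
from hypothesis import HealthCheck, settings

from fuzzymcda import TFN, load_study_fixture, load_study_weights

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_matrix():
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_weights():
    return load_study_weights()


def make_tfn(a: float, b: float, c: float) -> TFN:
    """Build a valid TFN from three unordered reals."""
    lo, m, u = sorted((a, b, c))
    return TFN(lo, m, u)
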