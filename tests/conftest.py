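import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NTS = "ACGU"


def random_seq(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list(NTS), size=L))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_seq(rng):
    def _make(L=41):
        return random_seq(rng, L)

    return _make
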