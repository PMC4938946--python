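import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return bytes(np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, n)]).decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20160709)


@pytest.fixture
def small_region(rng):
    from longcap.genome_io import TargetRegion

    n = 60_000
    return TargetRegion("reg", "reg", 0, n, random_sequence(rng, n))
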