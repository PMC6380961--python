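import numpy as np
import pytest

from epicdrem.genomic_io import PWM, GenomicRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_pwm():
    return PWM("uniform", np.full((3, 4), 0.25))


@pytest.fixture
def strong_pwm():
    """Sharply peaked 4-bp motif with consensus ACGT."""
    m = np.full((4, 4), 0.04)
    for i, b in enumerate([0, 1, 2, 3]):
        m[i, b] = 0.88
    return PWM("strong", m)


@pytest.fixture
def toy_genome(rng):
    """50 kb i.i.d. random genome on one chromosome."""
    bases = rng.choice(list("ACGT"), size=50_000)
    return {"chr1": "".join(bases)}


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
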