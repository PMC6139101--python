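import numpy as np
import pytest

from statetrait import StateVector, TraitVector


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_state(rng, span=1.0) -> StateVector:
    """A random state across (optionally beyond) the internal ranges."""
    return StateVector(
        E=float(rng.uniform(-span, span)),
        P=float(rng.uniform(0, span)),
        M=float(rng.uniform(0, span)),
        I=float(rng.uniform(0, span)),
        S=float(rng.uniform(-span, span)),
    )


def random_traits(rng) -> TraitVector:
    return TraitVector(*(float(x) for x in rng.uniform(0.0, 1.0, 4)))
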