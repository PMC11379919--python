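import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hmckit.sequence_io import ALPHABET, SequenceRecord, SequenceSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_set(rng: np.random.Generator, n: int, L: int, label="unknown") -> SequenceSet:
    """Uniform random equal-length RNA sequences."""
    codes = rng.integers(0, 4, size=(n, L))
    return SequenceSet(
        [
            SequenceRecord(f"{label[:3]}_{i}", "".join(ALPHABET[c] for c in row), label)
            for i, row in enumerate(codes)
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sets(rng):
    """A 20+20 random pair at L=15, enough for encoder round-trips."""
    return random_set(rng, 20, 15, "positive"), random_set(rng, 20, 15, "negative")
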