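import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def triad_sequence(index: int = 0) -> str:
    """A valid protein sequence carrying an E..K..C triad at 10-400 spacing.

    Varies with ``index`` so records from one organism get distinct residues.
    """
    letters = "ADFGHILMNPQRSTVWY"  # avoid extra E/K/C
    tail = "".join(letters[(index * 7 + i) % len(letters)] for i in range(20))
    return "M" + "A" * 15 + "E" + "G" * 30 + "K" + "L" * 30 + "C" + "V" * 10 + tail


@pytest.fixture
def make_triad_sequence():
    return triad_sequence
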