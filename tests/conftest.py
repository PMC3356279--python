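import numpy as np
import pytest

from kinnet import FocalSample, Individual


@pytest.fixture
def small_roster() -> list[Individual]:
    """Four animals in one group-year: a mother, another female, a male,
    and a juvenile."""
    return [
        Individual("A", "F", "adult", "G1", 2003),
        Individual("B", "F", "adult", "G1", 2003),
        Individual("C", "M", "adult", "G1", 2003),
        Individual("D", "F", "juvenile", "G1", 2003),
    ]


@pytest.fixture
def small_samples() -> list[FocalSample]:
    """Six focal samples over A-D with hand-checkable co-occurrence counts."""
    mk = lambda sid, focal, nbrs: FocalSample(sid, focal, frozenset(nbrs))
    return [
        mk("s1", "A", {"B"}),
        mk("s2", "A", {"B", "D"}),
        mk("s3", "B", set()),
        mk("s4", "C", {"D"}),
        mk("s5", "D", {"A"}),
        mk("s6", "C", set()),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120518)
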