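import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


@pytest.fixture
def make_dna(rng):
    def _make(n: int, gc: float = 0.5) -> str:
        return random_dna(n, rng, gc)

    return _make
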