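import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240322)
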