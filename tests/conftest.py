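import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture()
def random_dna(rng):
    def make(n: int, seed: int | None = None) -> str:
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(r.choice(list("ACGT"), size=n))

    return make
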