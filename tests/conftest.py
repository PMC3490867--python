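import numpy as np
import pytest

from polymirts.core_io import MatureMiRNA


@pytest.fixture(scope="session")
def let7a() -> MatureMiRNA:
    return MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
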