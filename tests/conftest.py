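import numpy as np
import pytest

from mitostruct import make_table1_fixture
from mitostruct.seq_io import Alignment


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


def random_alignment(rng, n=8, L=100, missing_rate=0.0, alphabet="ACGT"):
    """Random (unstructured) alignment, optionally with missing data."""
    chars = rng.choice(list(alphabet), size=(n, L))
    if missing_rate:
        mask = rng.random((n, L)) < missing_rate
        chars[mask] = rng.choice(["N", "-"], size=int(mask.sum()))
    ids = tuple(f"s{i}" for i in range(n))
    return Alignment(ids=ids, sequences=tuple("".join(row) for row in chars))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
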