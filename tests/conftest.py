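import numpy as np
import pytest

from rbpkit.seqio import STANDARD_AA, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_records():
    return [
        ProteinRecord("p1", "MKV", species="toy", label=1),
        ProteinRecord("p2", "HLTHAQSTLDAK", species="toy", label=0),
        ProteinRecord("p3", "ACDEFGHIKLMNPQRSTVWY", species="toy", label=0),
    ]


def random_sequence(rng, length):
    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture
def random_sequences(rng):
    return [random_sequence(rng, int(n)) for n in rng.integers(5, 81, size=30)]
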