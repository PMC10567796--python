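import numpy as np
import pytest

from cmkn.pam_kernel import NPFM, PAMParams
from cmkn.seq_io import DNA, EncodedSequence, encode_sequence, map_position


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_npfm(rng, alphabet_size=4, k=5):
    """A random valid nPFM: non-negative entries, unit-l2-norm columns."""
    m = rng.random((alphabet_size, k)) + 1e-3
    return NPFM(m / np.linalg.norm(m, axis=0, keepdims=True))


def random_circle_position(rng, length=100):
    p = int(rng.integers(1, length + 1))
    return map_position(p, length)


def random_encoded(rng, length, label=None, id="seq"):
    return encode_sequence(random_dna(rng, length), DNA, id=id, label=label)


@pytest.fixture
def params():
    return PAMParams(alpha=1.0, beta=1000.0, sigma=4.0, k=5)


@pytest.fixture
def small_params():
    return PAMParams(alpha=1.0, beta=14.4, sigma=2.0, k=3)
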