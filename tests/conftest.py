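import random

import pytest

from ecrmech.seqcore import NucleotideSequence


@pytest.fixture
def rng():
    return random.Random(0xECF)


def random_seq(rng, n, alphabet="ACGT", weights=None):
    if weights:
        return "".join(rng.choices(alphabet, weights=weights, k=n))
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def make_seq(rng):
    def _make(n, id="s", weights=None):
        return NucleotideSequence(id, random_seq(rng, n, weights=weights))
    return _make
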