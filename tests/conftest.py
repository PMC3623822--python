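import random

import pytest

from staligner.fm_index import Sequence


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0xC0FFEE)


@pytest.fixture
def ref_1kb(rng) -> Sequence:
    return Sequence("ref1k", random_dna(rng, 1000))
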