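import random

import pytest

DNA = "ACGT"


def random_instance(rng: random.Random, max_ls: int, max_lp: int, alphabet: str = DNA):
    """One (sequence, pattern) pair with lengths drawn uniformly."""
    ls = rng.randint(1, max_ls)
    lp = rng.randint(1, max_lp)
    seq = "".join(rng.choices(alphabet, k=ls))
    pat = "".join(rng.choices(alphabet, k=lp))
    return seq, pat


@pytest.fixture
def rng():
    return random.Random(20260920)
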