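import numpy as np
import pytest

from contigmend.core_io import SeqRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def corrupt(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Reference indel corruptor used by fixtures (independent of the
    synthetic module's implementation)."""
    out = []
    for ch in seq:
        u = rng.random()
        if u < rate / 2:
            continue
        out.append(ch)
        if u > 1 - rate / 2:
            out.append(BASES[rng.integers(0, 4)])
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def block_contigs(rng):
    """The nine-equal-block contig set x1=abcde, x2=fbcg, x3=hcdi."""
    blocks = {name: random_seq(rng, 100) for name in "abcdefghi"}
    x1 = SeqRecord("x1", "".join(blocks[c] for c in "abcde"))
    x2 = SeqRecord("x2", "".join(blocks[c] for c in "fbcg"))
    x3 = SeqRecord("x3", "".join(blocks[c] for c in "hcdi"))
    return [x1, x2, x3], blocks
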