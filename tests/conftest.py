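import itertools

import pytest

from casrxkit import synth
from casrxkit.seqio import Alphabet, SequenceRecord


@pytest.fixture
def transcript_600():
    return synth.random_transcript(42, 600)


@pytest.fixture
def valid_dr():
    return synth.SYNTHETIC_DR


def brute_force_max_pairs(seq: str, min_loop: int = 3, allow_wobble: bool = True) -> int:
    """Exhaustively enumerate every nested, loop-legal pairing; return max size.

    Independent of the dynamic program: structures are built explicitly and
    the maximum is taken over complete pair sets.
    """
    allowed = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_wobble:
        allowed |= {("G", "U"), ("U", "G")}

    def structures(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        yield from structures(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in allowed:
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield left | right | {(i, k)}

    return max((len(s) for s in structures(0, len(seq) - 1)), default=0)
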