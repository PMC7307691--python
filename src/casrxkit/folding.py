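"""Maximum base-pairing RNA secondary structure for hairpin/accessibility screens.

Candidate CasRx target windows are screened against self-structure: windows
predicted to fold into strong hairpins, or buried inside paired regions of the
local transcript fold, make poor targets. This module predicts structure with
a Nussinov-style dynamic program that maximizes the number of nested base
pairs subject to a minimum hairpin-loop length, with optional G.U wobble
pairs. It deliberately trades thermodynamic realism (nearest-neighbor free
energies, partition functions) for a parameter-light, exactly testable
predictor; "strong hairpin" is operationalized as the longest contiguous
helix (``max_stem``) in the maximum-pairing structure.

The traceback is deterministic: at each subinterval the 5'-most position is
paired whenever pairing attains the optimum, with the smallest admissible
partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import Alphabet, SequenceRecord, normalize_seq

DEFAULT_MIN_LOOP = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pairable_matrix(seq: str, allow_wobble: bool) -> np.ndarray:
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_wobble:
        pairs |= {("G", "U"), ("U", "G")}
    n = len(seq)
    mat = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(n):
            if (seq[i], seq[j]) in pairs:
                mat[i, j] = True
    return mat


@njit(cache=False)
def _fill(pairable: np.ndarray, min_loop: int) -> np.ndarray:  # pragma: no cover
    n = pairable.shape[0]
    table = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = table[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable[i, k]:
                    left = table[i + 1, k - 1] if k - 1 > i else 0
                    right = table[k + 1, j] if k + 1 < n and k < j else 0
                    v = 1 + left + right
                    if v > best:
                        best = v
            table[i, j] = best
    return table


def _traceback(table: np.ndarray, pairable: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    n = table.shape[0]
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = table[i, j]
        if target == 0:
            continue
        chosen = -1
        for k in range(i + min_loop + 1, j + 1):
            if not pairable[i, k]:
                continue
            left = table[i + 1, k - 1] if k - 1 > i else 0
            right = table[k + 1, j] if k < j else 0
            if 1 + left + right == target:
                chosen = k
                break
        if chosen >= 0:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return sorted(pairs)


def _max_stem(pairs: list[tuple[int, int]]) -> int:
    if not pairs:
        return 0
    pairset = set(pairs)
    best = 0
    for i, j in pairs:
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its helix
        run = 1
        while (i + run, j - run) in pairset:
            run += 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class FoldResult:
    """A predicted nested secondary structure.

    ``structure`` is dot-bracket notation; ``max_stem`` is the length (in bp)
    of the longest contiguous helix; ``unpaired_mask[i]`` is True when base i
    is unpaired.
    """

    seq: str
    structure: str
    pairs: tuple[tuple[int, int], ...]
    unpaired_mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure/sequence length mismatch")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    @property
    def max_stem(self) -> int:
        return _max_stem(list(self.pairs))

    @property
    def unpaired_fraction(self) -> float:
        return float(np.mean(self.unpaired_mask)) if len(self.seq) else 1.0


def fold_max_pairs(
    seq: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_wobble: bool = True,
) -> FoldResult:
    """Fold ``seq`` (RNA) into the maximum-pairing nested structure.

    Pairs (i, j) require at least ``min_loop`` unpaired bases between them.
    The traceback tie-break (pair the smallest i with its smallest optimal
    partner) makes the returned structure deterministic.
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    s = normalize_seq(seq, Alphabet.RNA)
    n = len(s)
    pairable = _pairable_matrix(s, allow_wobble)
    table = _fill(pairable, min_loop)
    pairs = _traceback(table, pairable, min_loop)
    assert len(pairs) == int(table[0, n - 1])
    structure = ["."] * n
    mask = np.ones(n, dtype=bool)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
        mask[i] = mask[j] = False
    return FoldResult(seq=s, structure="".join(structure), pairs=tuple(pairs), unpaired_mask=mask)


def hairpin_score(
    seq: str, min_loop: int = DEFAULT_MIN_LOOP, allow_wobble: bool = True
) -> int:
    """Longest contiguous helix (bp) in the max-pair fold of ``seq`` alone."""
    return fold_max_pairs(seq, min_loop=min_loop, allow_wobble=allow_wobble).max_stem


def accessibility(
    transcript: SequenceRecord | str,
    start: int,
    end: int,
    context_nt: int = 50,
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_wobble: bool = True,
) -> float:
    """Fraction of window bases unpaired in the local fold around the window.

    The window ``[start, end)`` is extended by ``context_nt`` on each side
    (clipped at transcript ends) and folded; the returned value is the
    fraction of the original window left unpaired. ``context_nt=0`` reduces
    to folding the window alone.
    """
    seq = transcript.seq if isinstance(transcript, SequenceRecord) else transcript
    seq = normalize_seq(seq, Alphabet.RNA)
    n = len(seq)
    if not (0 <= start < end <= n):
        raise ValueError(f"window [{start}, {end}) out of bounds for length {n}")
    if context_nt < 0:
        raise ValueError("context_nt must be >= 0")
    lo = max(0, start - context_nt)
    hi = min(n, end + context_nt)
    fold = fold_max_pairs(seq[lo:hi], min_loop=min_loop, allow_wobble=allow_wobble)
    window_mask = fold.unpaired_mask[start - lo : end - lo]
    return float(np.mean(window_mask))
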