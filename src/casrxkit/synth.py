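"""Seeded synthetic inputs: transcripts, cross count tables, count matrices.

Everything here is generated, never measured: the transcripts are random
nucleotide strings with a chosen GC fraction, the offspring tables are
binomial draws around a chosen inheritance probability, and the direct
repeat below is a synthetic stand-in that satisfies the structural rules
(36 nt, internal AAAAC motif) without claiming to be any experimentally
used repeat sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .knockdown import simulate_counts  # re-exported fixture generator
from .seqio import Alphabet, SequenceRecord

__all__ = [
    "SYNTHETIC_DR",
    "random_transcript",
    "cross_count_table",
    "simulate_counts",
]

# Synthetic 36-nt direct repeat with a 5'-proximal AAAAC motif; a structural
# placeholder for array assembly, NOT the CasRx repeat used in any experiment.
SYNTHETIC_DR = "CGAUAAAACGGUCUCGAAGGCAUUCGACCAGUGCGA"
assert len(SYNTHETIC_DR) == 36 and "AAAAC" in SYNTHETIC_DR


def random_transcript(
    seed: int,
    length: int = 600,
    gc: float = 0.5,
    transcript_id: str = "synthetic_tx",
    alphabet: Alphabet = Alphabet.RNA,
) -> SequenceRecord:
    """A seeded random mRNA-like sequence with expected GC fraction ``gc``."""
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = "ACGU" if Alphabet(alphabet) is Alphabet.RNA else "ACGT"
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list(bases), size=length, p=probs))
    return SequenceRecord(transcript_id, seq, alphabet, "seeded synthetic transcript")


def cross_count_table(
    seed: int,
    p_target: float,
    n_per_replicate: int = 150,
    n_replicates: int = 3,
    target_class: str = "transheterozygote",
    other_class: str = "other",
    group: str = "CasRx",
) -> pd.DataFrame:
    """Binomial offspring counts in the replicate structure of a fly cross.

    Each replicate vial yields ``n_per_replicate`` scored offspring of which
    Binomial(n, p_target) fall in the target class.
    """
    if not 0 <= p_target <= 1:
        raise ValueError("p_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        hits = int(rng.binomial(n_per_replicate, p_target))
        rows.append({"group": group, "replicate": rep, "class": target_class, "count": hits})
        rows.append(
            {"group": group, "replicate": rep, "class": other_class,
             "count": n_per_replicate - hits}
        )
    return pd.DataFrame(rows)
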