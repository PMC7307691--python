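"""Sequence and table I/O with strict alphabet normalization.

All design and folding math in this package runs on the RNA alphabet
(ACGU), because CasRx engages mRNA and base-pairing rules are RNA rules.
DNA is accepted on input and produced for cloning-facing output files.
Coordinates are 0-based, half-open internally; human-facing reports are
1-based, closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


_VALID_CHARS = {Alphabet.DNA: frozenset("ACGT"), Alphabet.RNA: frozenset("ACGU")}
_COMPLEMENT = {
    Alphabet.DNA: str.maketrans("ACGT", "TGCA"),
    Alphabet.RNA: str.maketrans("ACGU", "UGCA"),
}


def normalize_seq(seq: str, alphabet: Alphabet, *, context: str = "sequence") -> str:
    """Uppercase ``seq``, convert T<->U to ``alphabet``, reject anything else.

    Ambiguity codes (N, R, Y, ...) are rejected; the error names the
    offending character and its 1-based offset.
    """
    alphabet = Alphabet(alphabet)
    s = seq.upper()
    s = s.replace("U", "T") if alphabet is Alphabet.DNA else s.replace("T", "U")
    valid = _VALID_CHARS[alphabet]
    for pos, ch in enumerate(s):
        if ch not in valid:
            raise ValueError(
                f"{context}: illegal character {ch!r} at position {pos + 1} "
                f"for alphabet {alphabet.value}"
            )
    if not s:
        raise ValueError(f"{context}: empty sequence")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (transcript, spacer, DR or cassette)."""

    id: str
    seq: str
    alphabet: Alphabet = Alphabet.RNA
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        object.__setattr__(self, "id", self.id.strip())
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(
            self, "seq", normalize_seq(self.seq, self.alphabet, context=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.seq)

    def as_alphabet(self, alphabet: Alphabet) -> "SequenceRecord":
        alphabet = Alphabet(alphabet)
        if alphabet is self.alphabet:
            return self
        return SequenceRecord(
            id=self.id,
            seq=normalize_seq(self.seq, alphabet, context=f"record {self.id!r}"),
            alphabet=alphabet,
            description=self.description,
        )


def reverse_complement(seq: str, alphabet: Alphabet = Alphabet.RNA) -> str:
    """Watson-Crick reverse complement (RNA uses A<->U)."""
    alphabet = Alphabet(alphabet)
    s = normalize_seq(seq, alphabet)
    return s.translate(_COMPLEMENT[alphabet])[::-1]


def rna_to_dna(seq: str) -> str:
    return normalize_seq(seq, Alphabet.DNA)


def dna_to_rna(seq: str) -> str:
    return normalize_seq(seq, Alphabet.RNA)


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.RNA) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Records keep file order. Sequences are uppercased and T/U-normalized
    to ``alphabet``; empty files, duplicate ids and ambiguity codes raise
    ``ValueError`` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id.strip()
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                id=rid,
                seq=str(rec.seq),
                alphabet=alphabet,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA (LF line endings). Empty input is an error."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a header-ful TSV; missing required columns raise naming the column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in required or ():
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a TSV with optional '#'-prefixed provenance lines before the header."""
    with open(path, "w", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
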