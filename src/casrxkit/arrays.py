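"""Assembly and validation of the CasRx gRNA-array expression cassette.

A cassette is four tandem (direct repeat + spacer) units followed by one
extra direct repeat and a seven-thymine pol-III terminator:

    [DR 36nt][spacer 30nt] x 4  +  [DR 36nt]  +  TTTTTTT   = 307 nt

The direct repeat must be supplied by the user (it is validated for length
36 and the conserved 5'-AAAAC processing motif but never shipped as ground
truth). Output is the DNA sense strand as cloned downstream of a U6
promoter; promoter and vector sequence are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqio import (
    Alphabet,
    SequenceRecord,
    normalize_seq,
    rna_to_dna,
    write_fasta,
    write_table,
)

DR_LEN = 36
SPACER_LEN = 30
TERMINATOR_DNA = "T" * 7
DR_MOTIF = "AAAAC"


def validate_dr(dr_seq: str, strict_5p: bool = False) -> str:
    """Validate a direct repeat; returns the normalized RNA form.

    Rules: exactly 36 nt; contains the conserved AAAAC motif (with
    ``strict_5p`` the motif must start within the 5' half of the repeat).
    """
    rna = normalize_seq(dr_seq, Alphabet.RNA, context="direct repeat")
    if len(rna) != DR_LEN:
        raise ValueError(f"direct repeat must be {DR_LEN} nt, got {len(rna)}")
    idx = rna.find(DR_MOTIF)
    if idx < 0:
        raise ValueError(f"direct repeat lacks the conserved {DR_MOTIF} motif")
    if strict_5p and idx >= DR_LEN // 2:
        raise ValueError(
            f"{DR_MOTIF} motif at position {idx + 1} is outside the 5' half of the repeat"
        )
    return rna


@dataclass(frozen=True)
class GuideArray:
    """An assembled gRNA-array cassette with exact part annotations.

    ``annotations`` are (name, start, end, type) in 0-based half-open
    cassette coordinates; they tile the cassette with no gaps or overlaps.
    """

    dr_seq: str                       # RNA, 36 nt
    spacers: tuple[str, ...]          # RNA, 30 nt each
    cassette_dna: str
    annotations: tuple[tuple[str, int, int, str], ...]
    terminator: str = TERMINATOR_DNA

    def __post_init__(self) -> None:
        expect = len(self.spacers) * (DR_LEN + SPACER_LEN) + DR_LEN + len(self.terminator)
        if len(self.cassette_dna) != expect:
            raise ValueError("cassette length inconsistent with part list")
        pos = 0
        for name, start, end, _type in self.annotations:
            if start != pos:
                raise ValueError(f"annotation {name} leaves a gap/overlap at {pos}")
            pos = end
        if pos != len(self.cassette_dna):
            raise ValueError("annotations do not tile the cassette")

    @property
    def cassette_rna(self) -> str:
        """Transcript view of the cassette (pre-processing guide precursor)."""
        return normalize_seq(self.cassette_dna, Alphabet.RNA)

    def part_seq(self, name: str) -> str:
        for pname, start, end, _type in self.annotations:
            if pname == name:
                return self.cassette_dna[start:end]
        raise KeyError(name)


def assemble_array(
    spacers: Sequence[str],
    dr_seq: str,
    n_spacers: int = 4,
    spacer_len: int = SPACER_LEN,
) -> GuideArray:
    """Assemble DR-spacer repeats, the extra DR and the 7T terminator.

    With the default four 30-nt spacers the cassette is
    4*(36+30) + 36 + 7 = 307 nt and ends in TTTTTTT.
    """
    dr_rna = validate_dr(dr_seq)
    if len(spacers) != n_spacers:
        raise ValueError(f"expected {n_spacers} spacers, got {len(spacers)}")
    spacers_rna = []
    for i, sp in enumerate(spacers, start=1):
        rna = normalize_seq(sp, Alphabet.RNA, context=f"spacer {i}")
        if len(rna) != spacer_len:
            raise ValueError(f"spacer {i} must be {spacer_len} nt, got {len(rna)}")
        spacers_rna.append(rna)

    dr_dna = rna_to_dna(dr_rna)
    parts: list[tuple[str, str, str]] = []  # (name, type, dna)
    for i, sp in enumerate(spacers_rna, start=1):
        parts.append((f"DR{i}", "direct_repeat", dr_dna))
        parts.append((f"spacer{i}", "spacer", rna_to_dna(sp)))
    parts.append((f"DR{len(spacers_rna) + 1}", "direct_repeat", dr_dna))
    parts.append(("terminator", "terminator", TERMINATOR_DNA))

    cassette = "".join(dna for _, _, dna in parts)
    annotations = []
    pos = 0
    for name, ptype, dna in parts:
        annotations.append((name, pos, pos + len(dna), ptype))
        pos += len(dna)
    return GuideArray(
        dr_seq=dr_rna,
        spacers=tuple(spacers_rna),
        cassette_dna=cassette,
        annotations=tuple(annotations),
    )


def emit_construct(
    array: GuideArray,
    out_prefix: str | Path,
    record_id: str = "gRNA_array_cassette",
    header_lines: Sequence[str] = (),
) -> tuple[Path, Path]:
    """Write the cassette FASTA (DNA) and a feature TSV (1-based, closed).

    Returns (fasta_path, features_path). Feature coordinates re-slice the
    cassette to the exact part sequences.
    """
    prefix = str(out_prefix)
    if not prefix:
        raise ValueError("out_prefix must be non-empty")
    fasta_path = Path(f"{prefix}.fasta")
    feat_path = Path(f"{prefix}.features.tsv")
    description = " ".join(header_lines)
    write_fasta(
        [SequenceRecord(record_id, array.cassette_dna, Alphabet.DNA, description)],
        fasta_path,
    )
    rows = [
        {
            "part": name,
            "start_1based": start + 1,
            "end_1based": end,
            "type": ptype,
            "sequence": array.cassette_dna[start:end],
        }
        for name, start, end, ptype in array.annotations
    ]
    write_table(pd.DataFrame(rows), feat_path, header_lines=header_lines)
    return fasta_path, feat_path
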