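"""CasRx spacer enumeration, filtering, ranking, selection and off-target scan.

The design procedure slides a 30-nt window along the sense strand of the
target mRNA and keeps windows that (i) contain no poly-U run longer than
four bases, (ii) have GC content between 30% and 70% inclusive, (iii) are
not predicted to fold into a strong hairpin, and (iv) sit in a locally
accessible (largely unpaired) region of the transcript. Four passing,
well-separated windows are then selected per gene. The spacer is the
reverse complement of the target window, the orientation in which the
guide hybridizes to the mRNA.

The poly-U rule is applied by default to BOTH the target window and the
spacer: a U-run in the spacer itself would act as a pol-III terminator in
the U6-driven array, truncating the guide cassette.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

from . import folding
from .seqio import Alphabet, SequenceRecord, reverse_complement

FILTER_NAMES = ("poly_u", "gc", "hairpin", "accessibility")


@dataclass(frozen=True)
class DesignConfig:
    """All tunables of the spacer-design procedure.

    Defaults encode the published design constants (30-nt spacers, four per
    gene, GC in [30, 70]%, no poly-U run over 4 nt) plus this package's
    documented structure-screen settings.
    """

    spacer_len: int = 30
    n_spacers: int = 4
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_u_run: int = 4
    apply_u_filter_to: Literal["target", "spacer", "both"] = "both"
    max_stem: int = 5            # candidates with max_stem >= this fail the hairpin screen
    accessibility_min: float = 0.1
    context_nt: int = 50
    min_loop: int = 3
    allow_wobble: bool = True
    min_separation_nt: int = 50  # gap (nt) required between selected windows
    offtarget_max_mismatches: int = 3
    offtarget_seed_len: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("require 0 <= gc_min <= gc_max <= 100")
        if self.spacer_len < 1 or self.n_spacers < 1:
            raise ValueError("spacer_len and n_spacers must be >= 1")
        if self.apply_u_filter_to not in ("target", "spacer", "both"):
            raise ValueError("apply_u_filter_to must be target|spacer|both")
        if self.offtarget_max_mismatches > 5:
            raise ValueError("offtarget_max_mismatches must be <= 5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def max_base_run(seq: str, base: str) -> int:
    """Length of the longest homopolymer run of ``base`` in ``seq``."""
    best = 0
    for match in re.finditer(f"{base}+", seq):
        best = max(best, match.end() - match.start())
    return best


def gc_percent(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


@dataclass
class SpacerCandidate:
    """One 30-nt target window and the spacer derived from it.

    ``start``/``end`` are 0-based half-open on the sense mRNA. Structure
    fields (``max_stem``, ``access_frac``) and the per-filter ``passed`` map
    are populated by :func:`apply_filters`; ``score`` is the rank position
    assigned by :func:`rank_candidates` (0 = best).
    """

    transcript_id: str
    start: int
    end: int
    target_seq: str
    spacer_seq: str
    gc_percent: float
    u_run_target: int
    u_run_spacer: int
    max_stem: int | None = None
    access_frac: float | None = None
    passed: dict[str, bool] = field(default_factory=dict)
    score: float = math.nan
    transcript: SequenceRecord | None = field(default=None, repr=False, compare=False)

    @property
    def max_u_run(self) -> int:
        return max(self.u_run_target, self.u_run_spacer)

    @property
    def passed_all(self) -> bool:
        return bool(self.passed) and all(self.passed.values())


def enumerate_candidates(
    transcript: SequenceRecord, config: DesignConfig = DesignConfig()
) -> list[SpacerCandidate]:
    """All sliding windows of ``spacer_len`` (stride 1, 5'->3' order).

    Populates composition fields; structure fields are filled later by
    :func:`apply_filters`.
    """
    rna = transcript.as_alphabet(Alphabet.RNA)
    k = config.spacer_len
    if len(rna) < k:
        raise ValueError(
            f"transcript {rna.id!r} ({len(rna)} nt) is shorter than spacer_len={k}"
        )
    out: list[SpacerCandidate] = []
    for start in range(len(rna) - k + 1):
        window = rna.seq[start : start + k]
        spacer = reverse_complement(window, Alphabet.RNA)
        out.append(
            SpacerCandidate(
                transcript_id=rna.id,
                start=start,
                end=start + k,
                target_seq=window,
                spacer_seq=spacer,
                gc_percent=gc_percent(window),
                u_run_target=max_base_run(window, "U"),
                u_run_spacer=max_base_run(spacer, "U"),
                transcript=rna,
            )
        )
    return out


def _effective_u_run(cand: SpacerCandidate, config: DesignConfig) -> int:
    if config.apply_u_filter_to == "target":
        return cand.u_run_target
    if config.apply_u_filter_to == "spacer":
        return cand.u_run_spacer
    return cand.max_u_run


def apply_filters(
    candidates: Sequence[SpacerCandidate], config: DesignConfig = DesignConfig()
) -> list[SpacerCandidate]:
    """Set structure fields and per-filter pass flags on every candidate.

    A candidate passes iff its poly-U run is <= ``max_u_run`` (on the
    sequences named by ``apply_u_filter_to``), GC lies in
    [``gc_min``, ``gc_max``] inclusive, its hairpin ``max_stem`` is below
    ``max_stem``, and its accessibility is >= ``accessibility_min``.
    """
    for cand in candidates:
        if cand.max_stem is None:
            cand.max_stem = folding.hairpin_score(
                cand.target_seq, min_loop=config.min_loop, allow_wobble=config.allow_wobble
            )
        if cand.access_frac is None:
            if cand.transcript is None:
                raise ValueError(
                    "candidate lacks its source transcript; accessibility needs context"
                )
            cand.access_frac = folding.accessibility(
                cand.transcript,
                cand.start,
                cand.end,
                context_nt=config.context_nt,
                min_loop=config.min_loop,
                allow_wobble=config.allow_wobble,
            )
        cand.passed = {
            "poly_u": _effective_u_run(cand, config) <= config.max_u_run,
            "gc": config.gc_min <= cand.gc_percent <= config.gc_max,
            "hairpin": cand.max_stem < config.max_stem,
            "accessibility": cand.access_frac >= config.accessibility_min,
        }
    return list(candidates)


def _rank_key(cand: SpacerCandidate) -> tuple:
    return (cand.max_stem, -cand.access_frac, abs(cand.gc_percent - 50.0), cand.start)


def rank_candidates(
    candidates: Sequence[SpacerCandidate], config: DesignConfig = DesignConfig()
) -> list[SpacerCandidate]:
    """Deterministic total order over passing candidates.

    Ascending hairpin stem length, then descending accessibility, then GC
    closest to 50%, then 5'->3' position. The rank position is recorded as
    ``score``.
    """
    passing = [c for c in candidates if c.passed_all]
    if not passing:
        raise ValueError("no passing candidates to rank")
    ranked = sorted(passing, key=_rank_key)
    for pos, cand in enumerate(ranked):
        cand.score = float(pos)
    return ranked


def _min_gap(subset: Sequence[SpacerCandidate]) -> int:
    ordered = sorted(subset, key=lambda c: c.start)
    return min(b.start - a.end for a, b in zip(ordered, ordered[1:]))


def _failure_report(candidates: Sequence[SpacerCandidate], config: DesignConfig) -> str:
    counts = {name: sum(1 for c in candidates if c.passed and not c.passed[name])
              for name in FILTER_NAMES}
    n_pass = sum(1 for c in candidates if c.passed_all)
    detail = ", ".join(f"{k}={v}" for k, v in counts.items())
    return (
        f"only {n_pass} of {len(candidates)} candidates pass all filters "
        f"(need {config.n_spacers}); failures per filter: {detail}"
    )


def select_spacers(
    ranked: Sequence[SpacerCandidate], config: DesignConfig = DesignConfig()
) -> list[SpacerCandidate]:
    """Pick ``n_spacers`` non-overlapping windows spread along the transcript.

    Among the top-ranked feasible set (top 30 by rank, or all candidates if
    no feasible subset exists there), the subset of size ``n_spacers`` whose
    minimum pairwise gap is largest is chosen exhaustively, subject to every
    gap being >= ``min_separation_nt``; ties prefer better summed rank, then
    5'-most positions. When exhaustive search is infeasible a greedy pass in
    rank order is used. The result is returned 5'->3'.
    """
    n = config.n_spacers
    if len(ranked) < n:
        raise ValueError(_failure_report(ranked, config))
    if n == 1:
        return [min(ranked, key=lambda c: c.score)]

    def search(pool: Sequence[SpacerCandidate]) -> list[SpacerCandidate] | None:
        best: tuple | None = None
        best_subset: tuple[SpacerCandidate, ...] | None = None
        for subset in itertools.combinations(pool, n):
            gap = _min_gap(subset)
            if gap < config.min_separation_nt:
                continue
            key = (-gap, sum(c.score for c in subset),
                   tuple(sorted(c.start for c in subset)))
            if best is None or key < best:
                best, best_subset = key, subset
        return list(best_subset) if best_subset is not None else None

    pool = list(ranked[:30])
    chosen = search(pool)
    if chosen is None and len(ranked) > len(pool):
        if len(ranked) <= 40:
            chosen = search(ranked)
        else:  # greedy fallback in rank order
            picked: list[SpacerCandidate] = []
            for cand in ranked:
                gap_ok = all(
                    max(cand.start - o.end, o.start - cand.end) >= config.min_separation_nt
                    for o in picked
                )
                if gap_ok:
                    picked.append(cand)
                if len(picked) == n:
                    break
            chosen = picked if len(picked) == n else None
    if chosen is None:
        raise ValueError(
            f"no {n}-subset of passing candidates satisfies "
            f"min_separation_nt={config.min_separation_nt}; {_failure_report(ranked, config)}"
        )
    return sorted(chosen, key=lambda c: c.start)


def design_guides(
    transcript: SequenceRecord, config: DesignConfig = DesignConfig()
) -> tuple[list[SpacerCandidate], list[SpacerCandidate]]:
    """Full pipeline: enumerate, filter, rank, select.

    Returns (all candidates with filter annotations, the selected spacers).
    """
    candidates = enumerate_candidates(transcript, config)
    apply_filters(candidates, config)
    ranked = rank_candidates(candidates, config)
    selection = select_spacers(ranked, config)
    return candidates, selection


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def offtarget_scan(
    spacers: Sequence[SpacerCandidate],
    transcriptome: Sequence[SequenceRecord],
    max_mismatches: int = 3,
    seed_len: int = 12,
) -> pd.DataFrame:
    """Sense-strand Hamming-distance scan of target windows over a transcriptome.

    Exact k-mer seeding with verification: each query is split into
    ``max_mismatches + 1`` disjoint seeds (pigeonhole: any hit within the
    mismatch budget matches at least one seed exactly), seed hits are
    extended and verified by full Hamming comparison. The intended target
    window is flagged ``on_target``. No indels are modeled; this is a
    convenience screen, not a CasRx mismatch-tolerance model.
    """
    if not transcriptome:
        raise ValueError("transcriptome is empty")
    if max_mismatches > 5:
        raise ValueError("max_mismatches must be <= 5")
    records = [r.as_alphabet(Alphabet.RNA) for r in transcriptome]
    rows = []
    for cand in spacers:
        query = cand.target_seq
        k = len(query)
        n_seeds = max_mismatches + 1
        chunk = max(1, min(seed_len, k // n_seeds))
        seeds = [(off, query[off : off + chunk]) for off in range(0, n_seeds * chunk, chunk)]
        for rec in records:
            found: set[int] = set()
            for off, seed in seeds:
                pos = rec.seq.find(seed)
                while pos >= 0:
                    anchor = pos - off
                    if 0 <= anchor <= len(rec.seq) - k and anchor not in found:
                        mm = _hamming(query, rec.seq[anchor : anchor + k])
                        if mm <= max_mismatches:
                            found.add(anchor)
                            rows.append(
                                {
                                    "spacer": f"{cand.transcript_id}:{cand.start}-{cand.end}",
                                    "transcript_id": rec.id,
                                    "position": anchor,
                                    "mismatches": mm,
                                    "on_target": rec.id == cand.transcript_id
                                    and anchor == cand.start,
                                }
                            )
                    pos = rec.seq.find(seed, pos + 1)
    df = pd.DataFrame(rows, columns=["spacer", "transcript_id", "position", "mismatches", "on_target"])
    return df.sort_values(["spacer", "transcript_id", "position"]).reset_index(drop=True)


def candidates_to_frame(candidates: Sequence[SpacerCandidate]) -> pd.DataFrame:
    """Tabulate candidates (1-based closed coordinates for human-facing output)."""
    rows = []
    for c in candidates:
        row = {
            "transcript_id": c.transcript_id,
            "start_1based": c.start + 1,
            "end_1based": c.end,
            "target_seq": c.target_seq,
            "spacer_seq": c.spacer_seq,
            "gc_percent": round(c.gc_percent, 2),
            "u_run_target": c.u_run_target,
            "u_run_spacer": c.u_run_spacer,
            "max_stem": c.max_stem,
            "access_frac": None if c.access_frac is None else round(c.access_frac, 4),
            "score": c.score,
        }
        for name in FILTER_NAMES:
            row[f"pass_{name}"] = c.passed.get(name)
        row["pass_all"] = c.passed_all if c.passed else None
        rows.append(row)
    return pd.DataFrame(rows)
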