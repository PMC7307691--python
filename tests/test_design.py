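import dataclasses
import itertools
import re

import pytest

from casrxkit import synth
from casrxkit.design import (
    DesignConfig,
    apply_filters,
    candidates_to_frame,
    design_guides,
    enumerate_candidates,
    gc_percent,
    max_base_run,
    offtarget_scan,
    rank_candidates,
    select_spacers,
)
from casrxkit.seqio import Alphabet, SequenceRecord, reverse_complement


def _tx(seq: str, tid: str = "tx") -> SequenceRecord:
    return SequenceRecord(tid, seq, Alphabet.RNA)


def test_enumeration_count_and_order():
    tx = synth.random_transcript(1, 100)
    cands = enumerate_candidates(tx)
    assert len(cands) == 100 - 30 + 1
    assert [c.start for c in cands] == list(range(71))
    assert all(c.end - c.start == 30 for c in cands)


def test_single_window_and_spacer_orientation():
    cands = enumerate_candidates(_tx("A" * 30))
    assert len(cands) == 1 and (cands[0].start, cands[0].end) == (0, 30)
    assert cands[0].spacer_seq == "U" * 30
    tx = synth.random_transcript(3, 40)
    for c in enumerate_candidates(tx):
        assert c.spacer_seq == reverse_complement(c.target_seq)


def test_too_short_transcript_errors():
    with pytest.raises(ValueError, match="shorter"):
        enumerate_candidates(_tx("ACGU" * 7))


def test_poly_u_filter_on_target_and_spacer():
    # target window contains UUUUU -> fails regardless of orientation setting
    seq = "ACG" * 5 + "UUUUU" + "GCA" * 5  # J30 window w/ a 5-U run
    [cand] = enumerate_candidates(_tx(seq[:30]))
    apply_filters([cand], DesignConfig(apply_u_filter_to="target"))
    assert not cand.passed["poly_u"]
    # all-A target: clean in target orientation, poly-U spacer fails "both"
    [cand] = enumerate_candidates(_tx("A" * 30))
    apply_filters([cand], DesignConfig(apply_u_filter_to="target"))
    assert cand.passed["poly_u"] and cand.u_run_target == 0
    apply_filters([cand], DesignConfig(apply_u_filter_to="both"))
    assert not cand.passed["poly_u"]


def test_gc_bounds_inclusive():
    low = "G" * 9 + "A" * 21   # 30.0% -> passes (closed interval)
    lower = "G" * 8 + "A" * 22  # 26.7% -> fails
    for seq, expect in ((low, True), (lower, False)):
        [cand] = enumerate_candidates(_tx(seq))
        apply_filters([cand], DesignConfig())
        assert cand.passed["gc"] is expect
    assert gc_percent(low) == pytest.approx(30.0)


def test_filters_match_naive_recheck():
    """Every flag equals an independent re-derivation from the raw window."""
    tx = synth.random_transcript(11, 260)
    config = DesignConfig()
    cands = apply_filters(enumerate_candidates(tx, config), config)
    for c in cands:
        window = tx.seq[c.start : c.end]
        gc = 100.0 * len(re.findall("[GC]", window)) / 30
        u_t = max((len(m) for m in re.findall("U+", window)), default=0)
        u_s = max((len(m) for m in re.findall("U+", reverse_complement(window))), default=0)
        assert c.gc_percent == pytest.approx(gc)
        assert (c.u_run_target, c.u_run_spacer) == (u_t, u_s)
        assert c.passed["poly_u"] == (max(u_t, u_s) <= config.max_u_run)
        assert c.passed["gc"] == (config.gc_min <= gc <= config.gc_max)
        assert c.passed["hairpin"] == (c.max_stem < config.max_stem)
        assert c.passed["accessibility"] == (c.access_frac >= config.accessibility_min)
        assert c.passed_all == all(c.passed.values())


def test_tightening_thresholds_never_adds_candidates():
    tx = synth.random_transcript(13, 300)
    base = DesignConfig()
    cands = apply_filters(enumerate_candidates(tx, base), base)
    baseline = {c.start for c in cands if c.passed_all}
    tighter = [
        dataclasses.replace(base, gc_min=40.0, gc_max=60.0),
        dataclasses.replace(base, max_u_run=3),
        dataclasses.replace(base, max_stem=4),
        dataclasses.replace(base, accessibility_min=0.3),
    ]
    for config in tighter:
        apply_filters(cands, config)
        assert {c.start for c in cands if c.passed_all} <= baseline


def test_ranking_matches_naive_comparator():
    tx = synth.random_transcript(17, 220)
    config = DesignConfig()
    cands = apply_filters(enumerate_candidates(tx, config), config)
    ranked = rank_candidates(cands, config)
    naive = sorted(
        (c for c in cands if c.passed_all),
        key=lambda c: (c.max_stem, -c.access_frac, abs(c.gc_percent - 50.0), c.start),
    )
    assert [c.start for c in ranked] == [c.start for c in naive]
    assert [c.score for c in ranked] == [float(i) for i in range(len(ranked))]


def test_rank_tiebreak_is_position():
    a = _make_candidate(start=50, max_stem=2, access=0.5, gc=50.0)
    b = _make_candidate(start=10, max_stem=2, access=0.5, gc=50.0)
    c = _make_candidate(start=0, max_stem=4, access=0.9, gc=50.0)
    ranked = rank_candidates([a, b, c], DesignConfig())
    assert [x.start for x in ranked] == [10, 50, 0]  # stem first, then position


def _make_candidate(start, max_stem, access, gc):
    from casrxkit.design import SpacerCandidate

    n_gc = round(gc / 100 * 30)
    window = "G" * n_gc + "A" * (30 - n_gc)
    cand = SpacerCandidate(
        transcript_id="toy",
        start=start,
        end=start + 30,
        target_seq=window,
        spacer_seq=reverse_complement(window),
        gc_percent=gc,
        u_run_target=0,
        u_run_spacer=0,
        max_stem=max_stem,
        access_frac=access,
    )
    cand.passed = {k: True for k in ("poly_u", "gc", "hairpin", "accessibility")}
    return cand


def test_selection_matches_subset_brute_force():
    """Six-candidate toy set: selection equals exhaustive max-min-gap search."""
    starts = [0, 70, 120, 260, 340, 480]
    cands = [_make_candidate(s, 2, 0.5, 50.0) for s in starts]
    config = DesignConfig(min_separation_nt=50)
    chosen = select_spacers(rank_candidates(cands, config), config)

    def min_gap(subset):
        ordered = sorted(subset, key=lambda c: c.start)
        return min(b.start - a.end for a, b in zip(ordered, ordered[1:]))

    best = max(
        (s for s in itertools.combinations(cands, 4) if min_gap(s) >= 50),
        key=min_gap,
    )
    assert {c.start for c in chosen} == {c.start for c in best}
    assert [c.start for c in chosen] == sorted(c.start for c in chosen)


def test_selection_exact_four_and_failure_reporting():
    starts = [0, 100, 200, 300]
    cands = [_make_candidate(s, 2, 0.5, 50.0) for s in starts]
    config = DesignConfig(min_separation_nt=50)
    chosen = select_spacers(rank_candidates(cands, config), config)
    assert [c.start for c in chosen] == starts
    with pytest.raises(ValueError, match="failures per filter"):
        select_spacers(rank_candidates(cands[:3], config), config)


def test_design_pipeline_is_deterministic(transcript_600):
    _, sel1 = design_guides(transcript_600)
    _, sel2 = design_guides(transcript_600)
    assert [(c.start, c.spacer_seq) for c in sel1] == [(c.start, c.spacer_seq) for c in sel2]


def test_offtarget_scan_finds_planted_copy(transcript_600):
    _, selection = design_guides(transcript_600)
    cand = selection[0]
    # decoy transcript carrying a 2-mismatch copy of the target window
    mutated = list(cand.target_seq)
    mutated[5] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[5]]
    mutated[20] = {"A": "G", "C": "U", "G": "A", "U": "C"}[mutated[20]]
    decoy = SequenceRecord("decoy", "ACGU" * 10 + "".join(mutated) + "UGCA" * 10)
    txome = [transcript_600, decoy]

    hits2 = offtarget_scan([cand], txome, max_mismatches=2)
    decoy_hits = hits2[hits2.transcript_id == "decoy"]
    assert len(decoy_hits) == 1 and decoy_hits.iloc[0].mismatches == 2
    on = hits2[hits2.on_target]
    assert len(on) == 1 and on.iloc[0].position == cand.start

    hits1 = offtarget_scan([cand], txome, max_mismatches=1)
    assert hits1[hits1.transcript_id == "decoy"].empty


def test_offtarget_scan_matches_naive_hamming():
    tx = synth.random_transcript(23, 200, transcript_id="query_tx")
    decoys = [synth.random_transcript(29 + i, 150, transcript_id=f"d{i}") for i in range(3)]
    cands = enumerate_candidates(tx)[::40]
    txome = [tx] + decoys
    hits = offtarget_scan(cands, txome, max_mismatches=3)
    naive = set()
    for c in cands:
        for rec in txome:
            for pos in range(len(rec.seq) - 30 + 1):
                mm = sum(a != b for a, b in zip(c.target_seq, rec.seq[pos : pos + 30]))
                if mm <= 3:
                    naive.add((f"{c.transcript_id}:{c.start}-{c.end}", rec.id, pos, mm))
    got = {
        (r.spacer, r.transcript_id, r.position, r.mismatches)
        for r in hits.itertuples()
    }
    assert got == naive


def test_candidates_frame_columns(transcript_600):
    cands, _ = design_guides(transcript_600)
    df = candidates_to_frame(cands)
    assert len(df) == len(cands)
    assert {"start_1based", "spacer_seq", "pass_all", "pass_gc"} <= set(df.columns)
    assert df.start_1based.iloc[0] == 1  # 1-based closed reporting


def test_max_base_run():
    assert max_base_run("AUUUUGUU", "U") == 4
    assert max_base_run("ACGC", "U") == 0
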