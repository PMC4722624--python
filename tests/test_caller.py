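"""Caller logic: length inference, evidence geometry, aggregation, end-to-end.

Unit tests drive the evidence extractors with hand-constructed alignment
records; end-to-end tests run simulated reads through bwa and assert the
calls against simulator truth.
"""

import pytest

from tandemseek import (
    AlignedRead,
    CallerParams,
    ITDSpec,
    ReadGroup,
    aggregate_calls,
    collect_evidence,
    detect_itds,
    group_by_read,
    infer_itd_length,
    read_alignments,
    simulate_pairs_from_template,
)
from tandemseek.alignments import SAEntry, _parse_cigar_string as cig

from conftest import align_combination


# -- length inference -------------------------------------------------------


def test_infer_length_boundary_and_examples():
    assert infer_itd_length(100, 100) == 1  # c == s
    # a 30 bp duplication: clip at 28,608,261 realigning at 28,608,232
    assert infer_itd_length(28608261, 28608232) == 30
    with pytest.raises(ValueError):
        infer_itd_length(100, 101)  # realignment downstream: not an ITD


# -- constructed-record evidence geometry -----------------------------------


def primary(name, pos, cigar, seq, sa=(), strand="+", mate=1, mapq=60):
    return AlignedRead(
        name, mate == 1, strand, "primary", None if False else "c", pos,
        cig(cigar), seq, mapq, tuple(sa),
    )


def make_window():
    from tandemseek.amplicon import synthetic_window

    return synthetic_window()


def test_sa_split_right_clip_gives_exact_length():
    w = make_window()
    off = len(w.left_flank)  # alignments in slice coordinates
    # duplication [100, 249]: primary aligned to 1..249 with 26 clipped bases
    # realigning at 100 (read covers query 1..249 primary, 250..275 supp)
    seq = w.slice(1, 249) + w.slice(100, 125)
    rec = primary(
        "r", off + 1, "249M26S", seq,
        sa=[SAEntry("c", off + 100, "+", cig("249S26M"), 60)],
    )
    (ev,) = collect_evidence({"r": ReadGroup("r", {1: rec}, [])}, w, roi_ref_start=off + 1)
    assert ev.method == "softclip_realign"
    assert ev.length == 150 and ev.position == 100


def test_sa_split_query_overlap_correction():
    w = make_window()
    off = len(w.left_flank)
    # aligner extended both pieces through 4 bp of chance junction homology:
    # primary covers query 1..253 (ref 1..253), supp covers query 250..275
    # realigning at ref 100; naive c - s + 1 overcounts by the 4-base overlap
    seq = w.slice(1, 249) + w.slice(100, 125)
    rec = primary(
        "r", off + 1, "253M22S", seq,
        sa=[SAEntry("c", off + 100, "+", cig("249S26M"), 60)],
    )
    (ev,) = collect_evidence({"r": ReadGroup("r", {1: rec}, [])}, w, roi_ref_start=off + 1)
    assert ev.length == (253 - 100 + 1) - 4 == 150


def test_sa_on_opposite_strand_is_ignored():
    w = make_window()
    off = len(w.left_flank)
    seq = w.slice(1, 249) + w.slice(100, 125)
    rec = primary(
        "r", off + 1, "249M26S", seq,
        sa=[SAEntry("c", off + 100, "-", cig("249S26M"), 60)],
    )
    assert collect_evidence({"r": ReadGroup("r", {1: rec}, [])}, w, roi_ref_start=off + 1) == []


def test_closure_right_clip_past_roi_end():
    w = make_window()
    off = len(w.left_flank)
    n = len(w)
    # duplication (p=190, L=150): alignment runs 62 bp into the right flank,
    # clipped tail is the last 12 ROI bases
    seq = w.slice(77, 339) + w.roi_seq[189:]
    rec = primary("r", off + 77, "263M12S", seq)
    (ev,) = collect_evidence({"r": ReadGroup("r", {1: rec}, [])}, w, roi_ref_start=off + 1)
    assert ev.length == (339 - n) + 12 == 150
    assert ev.position == n - 12 + 1 == 190


def test_wild_type_adapter_clips_yield_nothing():
    w = make_window()
    off = len(w.left_flank)
    # wild-type read: ROI then adapter junk soft-clipped at the ROI end
    junk = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAA"
    rec1 = primary("r", off + 1, f"201M{len(junk)}S", w.roi_seq + junk)
    junk2 = junk[:70]
    rec2 = primary(
        "r", off + 1, f"{len(junk2)}S201M", junk2 + w.roi_seq, strand="-", mate=2
    )
    groups = {"r": ReadGroup("r", {1: rec1, 2: rec2}, [])}
    assert collect_evidence(groups, w, roi_ref_start=off + 1) == []


def test_pure_insertion_query_gap():
    w = make_window()
    off = len(w.left_flank)
    ins = "TTACGGATCCGTAAGCTTGGAATTCCGGATCCAAGCTTGG"  # 40 bp foreign
    # read = ROI[1..100] + INS + ROI[101..201]; split with a 40 bp query gap
    seq = w.slice(1, 100) + ins + w.slice(101, 201)
    rec = primary(
        "r", off + 1, "100M141S", seq,
        sa=[SAEntry("c", off + 101, "+", cig("140S101M"), 60)],
    )
    (ev,) = collect_evidence({"r": ReadGroup("r", {1: rec}, [])}, w, roi_ref_start=off + 1)
    assert ev.method == "pair_geometry"
    assert ev.length == 40
    assert ev.position == 100


def test_pure_insertion_pair_clip_comparison():
    w = make_window()
    off = len(w.left_flank)
    ins = "TTACGGATCCGTAAGCTTGGAATTCCGGATCCAAGCTTGGTTACGGATCCGTAAGCTTGGAATTCCGGATCCAAGCTTGG"
    # insertion of 80 foreign bp after ROI position 190: downstream anchor too
    # short for a split alignment on either mate; both clip at 190
    m1 = w.slice(1, 190) + ins + w.slice(191, 195)
    m2 = w.slice(7, 190) + ins + w.slice(191, 201)
    r1 = primary("r", off + 1, "190M85S", m1, mate=1)
    r2 = primary("r", off + 7, "184M91S", m2, strand="-", mate=2)
    evs = collect_evidence({"r": ReadGroup("r", {1: r1, 2: r2}, [])}, w, roi_ref_start=off + 1)
    assert len(evs) == 2
    assert {e.direction for e in evs} == {"+", "-"}
    assert all(e.length == 80 and e.method == "pair_geometry" for e in evs)
    assert not any(e.low_confidence for e in evs)


def test_pure_insertion_single_mate_is_low_confidence():
    w = make_window()
    off = len(w.left_flank)
    ins = "TTACGGATCCGTAAGCTTGGAATTCCGGATCCAAGCTTGG"
    m1 = w.slice(1, 150) + ins + w.slice(151, 201)
    r1 = primary("r", off + 1, "150M91S", m1[:241], mate=1)
    evs = collect_evidence({"r": ReadGroup("r", {1: r1}, [])}, w, roi_ref_start=off + 1)
    assert len(evs) == 1 and evs[0].low_confidence
    assert evs[0].length == 40


def test_opposed_clips_are_not_an_insertion_signature():
    w = make_window()
    off = len(w.left_flank)
    # clips at opposite amplicon boundaries pointing away from each other
    junk = "TTACGGATCCGTAAGCTTGGAATTCCGGATCCAAGCTTGG"
    r1 = primary("r", off + 1, "201M40S", w.roi_seq + junk, mate=1)
    r2 = primary("r", off + 1, "40S201M", junk + w.roi_seq, strand="-", mate=2)
    assert collect_evidence({"r": ReadGroup("r", {1: r1, 2: r2}, [])}, w, roi_ref_start=off + 1) == []


# -- aggregation ------------------------------------------------------------


def test_aggregate_merges_directions_and_computes_vaf():
    from tandemseek.caller import ITDEvidence

    w = make_window()
    evs = [
        ITDEvidence("a", 1, "+", "softclip_realign", 149, 100, 100, 50),
        ITDEvidence("a", 2, "-", "softclip_realign", 149, 100, 100, 50),
    ]
    recs = [
        primary("a", len(w.left_flank) + 1, "275M", None, mate=1),
        primary("a", len(w.left_flank) + 1, "275M", None, mate=2, strand="-"),
        primary("b", len(w.left_flank) + 1, "201M", None, mate=1),
        primary("b", len(w.left_flank) + 1, "201M", None, mate=2, strand="-"),
    ]
    calls = aggregate_calls(evs, recs, w, roi_ref_start=len(w.left_flank) + 1)
    assert len(calls) == 1
    call = calls[0]
    assert call.support_forward == 1 and call.support_reverse == 1
    assert call.depth == 4
    assert call.vaf == pytest.approx(0.5)
    # this window has w.slice(99) == w.slice(149): the duplication is
    # coordinate-ambiguous and the call is left-aligned one base
    assert call.position == w.roi_start + 99 - 1
    assert call.inserted_seq == w.slice(99, 148)


def test_aggregate_keeps_distinct_clones_separate():
    from tandemseek.caller import ITDEvidence

    w = make_window()
    off = len(w.left_flank) + 1
    evs = [
        ITDEvidence("a", 1, "+", "softclip_realign", 202, 140, 140, 63),
        ITDEvidence("b", 1, "+", "softclip_realign", 203, 150, 150, 54),
    ]
    recs = [
        primary("a", off, "275M", None),
        primary("b", off, "275M", None),
    ]
    calls = aggregate_calls(evs, recs, w, roi_ref_start=off)
    assert [(c.length) for c in calls] == [63, 54]
    assert calls[0].position < calls[1].position


# -- end-to-end through the aligner -----------------------------------------


def test_end_to_end_single_call_exact_length(window, indexed_reference, tmp_path):
    spec = ITDSpec(101, 100, 0.5, 40)
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    calls = detect_itds(sam, window)
    assert len(calls) == 1
    assert calls[0].length == 100
    roi_pos = calls[0].position - window.roi_start + 1
    assert 101 - 100 <= roi_pos <= 101 + 100


def test_end_to_end_wild_type_only_no_calls(window, indexed_reference, tmp_path):
    spec = ITDSpec(101, 100, 0.0, 40)
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    assert detect_itds(sam, window) == []


def test_end_to_end_bam_input_equals_sam_input(window, indexed_reference, tmp_path):
    spec = ITDSpec(150, 60, 0.5, 40)
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    bam = align_combination(window, indexed_reference, tmp_path, spec, to_bam=True)
    assert detect_itds(sam, window) == detect_itds(bam, window)


def test_end_to_end_single_read_pair_clone(window, indexed_reference, tmp_path):
    # one ITD pair among 2000 total pairs still yields a call
    spec = ITDSpec(150, 60, 1 / 2000, 2000)
    assert spec.n_itd_pairs == 1
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    calls = detect_itds(sam, window)
    assert len(calls) == 1
    assert calls[0].length == 60
    assert calls[0].support == 2  # both mates of the single pair
    assert calls[0].vaf == pytest.approx(2 / calls[0].depth)


def test_end_to_end_burden_recovery(window, indexed_reference, tmp_path):
    spec = ITDSpec(150, 60, 0.5, 400)
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    (call,) = detect_itds(sam, window)
    assert call.support_forward == 200 and call.support_reverse == 200
    assert call.vaf == pytest.approx(0.5, abs=0.02)
    assert call.vaf == call.support / call.depth


def test_end_to_end_two_clone_mixture(window, indexed_reference, tmp_path):
    """Two ITD clones (63 and 54 bp) at unequal burdens are both reported."""
    import subprocess

    fa, _ = indexed_reference
    from tandemseek import build_itd_allele, simulate_combination

    fq1, fq2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    with open(fq1, "w") as h1, open(fq2, "w") as h2:
        simulate_combination(
            window, ITDSpec(140, 63, 1.0, 30), None, None, _handles=(h1, h2)
        )
        simulate_combination(
            window, ITDSpec(150, 54, 1.0, 12), None, None, _handles=(h1, h2)
        )
        simulate_combination(
            window, ITDSpec(1, 1, 0.0, 158), None, None, _handles=(h1, h2)
        )
    sam = tmp_path / "mix.sam"
    with open(sam, "w") as out:
        subprocess.run(
            ["bwa", "mem", str(fa), str(fq1), str(fq2)],
            stdout=out, stderr=subprocess.DEVNULL, check=True,
        )
    calls = detect_itds(sam, window)
    lengths = sorted(c.length for c in calls)
    assert lengths == [54, 63]
    by_len = {c.length: c for c in calls}
    assert by_len[63].support > by_len[54].support


def test_deterministic_call_list(window, indexed_reference, tmp_path):
    spec = ITDSpec(150, 60, 0.5, 40)
    sam = align_combination(window, indexed_reference, tmp_path, spec)
    assert detect_itds(sam, window) == detect_itds(sam, window)
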