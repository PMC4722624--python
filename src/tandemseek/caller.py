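"""Soft-clip based internal-tandem-duplication caller.

The detection principle: an ITD that is too long, or sits too close to an
amplicon end, cannot be aligned as a simple insertion — the duplicated bases
are soft-clipped instead, and a split-read aligner realigns them to the same
locus.  The caller therefore inspects every primary alignment for terminal
soft clips and derives duplication evidence from three geometries:

1. *Soft clip + realignment* (``softclip_realign``): the clipped bases
   realign upstream at the same locus (aligner SA tag / supplementary
   records).  With clip point ``c`` (last aligned base before a right clip)
   and realignment start ``s``, the duplication spans ``[s, c]`` and its
   length is ``L = c - s + 1``.  When the aligner extends either piece
   through chance micro-homology at the junction, the two alignments overlap
   on the query; the overlap is subtracted so ``L`` stays exact.

2. *Amplicon-end closure* (also ``softclip_realign``): a duplication whose
   first copy runs past the region of interest (ROI) end leaves a primary
   alignment that extends into the downstream flank and a clipped tail equal
   to the terminal ROI segment.  If the clipped prefix of length ``m``
   equals the last ``m`` ROI bases, the duplication closes the amplicon:
   ``L = (c - roi_end) + m``.  Wild-type reads never align past the ROI end
   (their tails are adapter), so this geometry is null-safe.

3. *Pure insertion* (``pair_geometry``): inserted sequence of unknown origin
   has no realignment.  It appears either as a query gap between two
   adjacent split pieces of one read, or as mutually consistent clip points
   on the two mates of a pair whose clipped excess does not match the locus.

Analysis is per read and per direction, so a single supporting read pair
suffices for a call; multiple distinct (position, length) clusters yield
multiple calls (multi-clone detection).  No reporting threshold is applied
here — every call with at least one supporting read is emitted, and clinical
thresholds are annotation labels applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

from .amplicon import ReferenceWindow
from .alignments import (
    AlignedRead,
    ReadGroup,
    SoftClip,
    extract_soft_clips,
    group_by_read,
    read_alignments,
)

__all__ = [
    "CallerParams",
    "ITDEvidence",
    "ITDCall",
    "infer_itd_length",
    "collect_evidence",
    "detect_pure_insertion",
    "aggregate_calls",
    "detect_itds",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunable caller parameters.

    min_clip
        Shortest terminal soft clip examined at all (bp).  Discrimination of
        adapter clips from ITD clips is by content (clipped bases must
        realign or match the locus), so this is a noise floor, not the
        sensitivity limit.
    min_itd_length
        Shortest duplication reported (bp).  Shorter ITDs align as plain
        I-CIGAR insertions that general-purpose small-variant callers handle;
        this caller's domain is the soft-clipped regime.
    closure_min_match
        Minimum clipped bases that must match the ROI terminus for
        amplicon-end closure evidence.
    min_mapq_primary / min_mapq_secondary
        Mapping-quality floors.  Split realignments are frequently MAPQ 0,
        hence the separate (default 0) secondary threshold.
    anchor_width
        Bases of reference continuation required to anchor the far side of a
        pure-insertion breakpoint.
    """

    min_clip: int = 4
    min_itd_length: int = 15
    closure_min_match: int = 4
    min_mapq_primary: int = 1
    min_mapq_secondary: int = 0
    anchor_width: int = 15


@dataclass(frozen=True)
class ITDEvidence:
    """One read's worth of duplication evidence (ROI coordinates)."""

    read_name: str
    mate: int
    direction: str  # '+' forward, '-' reverse
    method: str  # softclip_realign | pair_geometry
    clip_point: int  # ROI coordinate of the aligned base adjacent to the clip
    realign_start: int | None  # ROI coordinate s of the realignment (None for pair_geometry)
    position: int  # ROI coordinate assigned to the duplication start
    length: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("inferred length must be >= 1")
        if self.method == "softclip_realign" and self.realign_start is not None:
            if self.realign_start > self.clip_point:
                raise ValueError("realignment must start at or upstream of the clip point")


@dataclass(frozen=True)
class ITDCall:
    """An aggregated ITD call in genomic coordinates."""

    ref_name: str
    position: int  # 1-based genomic, left-aligned duplication start
    length: int
    inserted_seq: str | None  # None when not resolvable (symbolic ALT downstream)
    support_forward: int
    support_reverse: int
    depth: int
    vaf: float
    method: str = "softclip_realign"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.support_forward + self.support_reverse < 1:
            raise ValueError("a call requires at least one supporting read")
        if self.depth < self.support_forward + self.support_reverse:
            raise ValueError("depth cannot be below total support")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError("VAF must lie in (0, 1]")

    @property
    def support(self) -> int:
        return self.support_forward + self.support_reverse


def infer_itd_length(clip_point_ref: int, realign_start_ref: int) -> int:
    """Duplication length from clip point ``c`` and realignment start ``s``.

    The duplicated segment spans ``[s, c]`` inclusively, so ``L = c - s + 1``.
    A realignment downstream of the clip point is not a duplication; callers
    should discard such evidence rather than call this.
    """
    if realign_start_ref > clip_point_ref:
        raise ValueError("realignment start lies downstream of the clip point")
    return clip_point_ref - realign_start_ref + 1


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------


def _sa_split_evidence(
    rec: AlignedRead, clip: SoftClip, roi_offset: int, params: CallerParams
) -> ITDEvidence | None:
    """Soft clip whose bases realign upstream via the SA tag."""
    for sa in rec.sa:
        if sa.ref_name != rec.ref_name or sa.strand != rec.strand:
            continue
        if sa.mapq < params.min_mapq_secondary:
            continue
        if clip.side == "right":
            c = clip.clip_point_ref
            s = sa.ref_start
            if s > c or sa.query_start <= rec.query_start:
                continue  # not an upstream realignment of the clipped tail
            overlap = max(0, rec.query_end - sa.query_start + 1)
            L = infer_itd_length(c, s) - overlap
        else:
            c = clip.clip_point_ref
            e = sa.ref_end
            if e < c or sa.query_end >= rec.query_end:
                continue
            overlap = max(0, sa.query_end - rec.query_start + 1)
            L = e - c + 1 - overlap
            s = c
        if L < 1:
            continue
        return ITDEvidence(
            rec.name, rec.mate, rec.strand, "softclip_realign",
            clip_point=c - roi_offset,
            realign_start=(s - roi_offset) if clip.side == "right" else (c - roi_offset),
            position=(s if clip.side == "right" else c) - roi_offset,
            length=L,
        )
    return None


def _closure_evidence(
    rec: AlignedRead,
    clip: SoftClip,
    window: ReferenceWindow,
    roi_offset: int,
    params: CallerParams,
) -> ITDEvidence | None:
    """Duplication whose first copy runs past an ROI end.

    The primary alignment then extends into the flank and the clipped bases
    are the ROI terminus; matching them against it closes the amplicon and
    fixes the length exactly.
    """
    if clip.clipped_seq is None:
        return None
    n = len(window)
    c = clip.clip_point_ref - roi_offset  # ROI coordinate
    if clip.side == "right" and c > n:
        tail = window.roi_seq
        for m in range(min(clip.clip_length, n), params.closure_min_match - 1, -1):
            if clip.clipped_seq[:m] == tail[n - m:]:
                L = (c - n) + m
                s = n - m + 1
                return ITDEvidence(
                    rec.name, rec.mate, rec.strand, "softclip_realign",
                    clip_point=c, realign_start=s, position=s, length=L,
                )
    elif clip.side == "left" and c < 1:
        head = window.roi_seq
        for m in range(min(clip.clip_length, n), params.closure_min_match - 1, -1):
            if clip.clipped_seq[-m:] == head[:m]:
                L = (1 - c) + m
                return ITDEvidence(
                    rec.name, rec.mate, rec.strand, "softclip_realign",
                    clip_point=c, realign_start=c, position=c, length=L,
                )
    return None


def _insert_gap_evidence(
    rec: AlignedRead, roi_offset: int, params: CallerParams
) -> ITDEvidence | None:
    """Pure insertion seen as a query gap between adjacent split pieces."""
    for sa in rec.sa:
        if sa.ref_name != rec.ref_name or sa.strand != rec.strand:
            continue
        # downstream continuation: supplementary picks up right after the
        # primary on the reference, with unaligned (inserted) query between
        if sa.query_start > rec.query_end and 0 <= sa.ref_start - rec.ref_end - 1 <= 1:
            gap = sa.query_start - rec.query_end - 1
            if gap >= 1:
                return ITDEvidence(
                    rec.name, rec.mate, rec.strand, "pair_geometry",
                    clip_point=rec.ref_end - roi_offset,
                    realign_start=None,
                    position=rec.ref_end - roi_offset,
                    length=gap,
                )
    return None


def _foreign_insert_length(
    clip: SoftClip, window: ReferenceWindow, roi_offset: int, params: CallerParams
) -> int | None:
    """Length of foreign sequence at the start of a clip, if the clip
    eventually resumes the reference.

    For a right clip at ``c`` the true continuation is the reference from
    ``c + 1``; the number of leading clip bases before that continuation is
    the inserted length.  Returns None when no continuation is found or the
    leading bases look like locus sequence (then it is not an insertion of
    unknown origin).
    """
    if clip.clipped_seq is None:
        return None
    seq = clip.clipped_seq
    k = len(seq)
    c = clip.clip_point_ref - roi_offset
    n = len(window)
    lo = 1 - len(window.left_flank)
    hi = n + len(window.right_flank)
    for m in range(1, k):
        w = min(params.anchor_width, k - m)
        if w < 4:
            break
        if clip.side == "right":
            a, b = c + 1, c + w
            if a < lo or b > hi:
                break
            ref = window.slice(a, b)
            probe = seq[m:m + w]
        else:
            a, b = c - w, c - 1
            if a < lo or b > hi:
                break
            ref = window.slice(a, b)
            probe = seq[k - m - w:k - m]
        if probe == ref:
            ins = seq[:m] if clip.side == "right" else seq[k - m:]
            # unknown origin: the inserted bases must not be locus sequence
            whole = window.slice(lo, hi)
            if ins[: min(len(ins), 20)] in whole:
                return None
            return m
    return None


def collect_evidence(
    groups: dict[str, ReadGroup] | Iterable[ReadGroup],
    window: ReferenceWindow,
    params: CallerParams = CallerParams(),
    roi_ref_start: int | None = None,
) -> list[ITDEvidence]:
    """Per-read, per-direction duplication evidence from grouped alignments.

    ``roi_ref_start`` is the 1-based position of the ROI start on the
    reference the alignments use (``window.roi_start`` for genome-aligned
    input; ``len(left_flank) + 1`` for a windowed reference slice).
    Reads without qualifying clips contribute nothing.
    """
    if roi_ref_start is None:
        roi_ref_start = window.roi_start
    roi_offset = roi_ref_start - 1  # contig coord - offset = ROI coord
    if isinstance(groups, dict):
        groups = groups.values()
    evidence: list[ITDEvidence] = []
    for g in groups:
        evidence.extend(_group_evidence(g, window, params, roi_offset))
    return evidence


def _group_evidence(
    g: ReadGroup, window: ReferenceWindow, params: CallerParams, roi_offset: int
) -> list[ITDEvidence]:
    out: list[ITDEvidence] = []
    unexplained: dict[int, tuple[AlignedRead, SoftClip]] = {}
    for mate, rec in sorted(g.primary.items()):
        if rec.mapq < params.min_mapq_primary:
            continue
        found_for_mate = False
        for clip in extract_soft_clips(rec, params.min_clip):
            ev = _sa_split_evidence(rec, clip, roi_offset, params)
            if ev is None:
                ev = _closure_evidence(rec, clip, window, roi_offset, params)
            if ev is not None:
                if ev.length >= params.min_itd_length:
                    out.append(ev)
                found_for_mate = True  # clip explained either way
                continue
            unexplained[mate] = (rec, clip)
        if not found_for_mate:
            ev = _insert_gap_evidence(rec, roi_offset, params)
            if ev is not None and ev.length >= params.min_itd_length:
                out.append(ev)
                unexplained.pop(mate, None)
    pair_ev = detect_pure_insertion(unexplained, window, params, roi_offset)
    out.extend(e for e in pair_ev if e.length >= params.min_itd_length)
    # one evidence item per (mate, direction, position, length)
    seen: set[tuple] = set()
    uniq = []
    for e in out:
        key = (e.mate, e.direction, e.position, e.length)
        if key not in seen:
            seen.add(key)
            uniq.append(e)
    return uniq


def detect_pure_insertion(
    unexplained: dict[int, tuple[AlignedRead, SoftClip]],
    window: ReferenceWindow,
    params: CallerParams = CallerParams(),
    roi_offset: int = 0,
) -> list[ITDEvidence]:
    """Pure-insertion evidence from clip-point comparison across a read pair.

    Takes the unexplained terminal clips of the two mates (no realignment of
    the clipped bases anywhere at the locus).  If both mates clip at
    mutually consistent points (within 1 bp) and the clipped excess resumes
    the reference after a foreign stretch of identical inferred length, the
    pair supports an insertion of unknown origin.  A single informative mate
    yields the same evidence flagged low-confidence.  Clip points at the
    very amplicon boundaries are ignored (adapter read-through geometry).
    """
    n = len(window)
    cands: list[tuple[AlignedRead, SoftClip, int]] = []
    for mate, (rec, clip) in sorted(unexplained.items()):
        c = clip.clip_point_ref - roi_offset
        if not 2 <= c <= n - 1:
            continue
        m = _foreign_insert_length(clip, window, roi_offset, params)
        if m is not None and m >= 1:
            cands.append((rec, clip, m))
    if not cands:
        return []
    out = []
    if len(cands) == 2:
        (r1, c1, m1), (r2, c2, m2) = cands
        consistent = (
            abs((c1.clip_point_ref) - (c2.clip_point_ref)) <= 1 and m1 == m2
        )
        if consistent:
            for rec, clip, m in cands:
                pos = clip.clip_point_ref - roi_offset
                out.append(
                    ITDEvidence(
                        rec.name, rec.mate, rec.strand, "pair_geometry",
                        clip_point=pos, realign_start=None,
                        position=min(c1.clip_point_ref, c2.clip_point_ref) - roi_offset,
                        length=m,
                    )
                )
            return out
    # single informative mate (or inconsistent pair): low-confidence fallback
    for rec, clip, m in cands:
        pos = clip.clip_point_ref - roi_offset
        out.append(
            ITDEvidence(
                rec.name, rec.mate, rec.strand, "pair_geometry",
                clip_point=pos, realign_start=None, position=pos,
                length=m, low_confidence=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _left_align(window: ReferenceWindow, pos: int, length: int) -> int:
    """Leftmost equivalent start of a tandem duplication (repeat ambiguity)."""
    lo = 1 - len(window.left_flank)
    try:
        while pos > lo and window.slice(pos - 1, pos - 1) == window.slice(
            pos + length - 1, pos + length - 1
        ):
            pos -= 1
    except ValueError:
        pass
    return pos


def aggregate_calls(
    evidence: Sequence[ITDEvidence],
    groups: dict[str, ReadGroup] | Sequence[AlignedRead],
    window: ReferenceWindow,
    roi_ref_start: int | None = None,
) -> list[ITDCall]:
    """Merge per-read evidence into calls with support, depth and VAF.

    Evidence items agreeing on (left-aligned position, length) merge into a
    single call; support is counted per direction as distinct (read, mate)
    units; depth is the number of primary mate records overlapping the call
    position; VAF = support / depth.
    """
    if roi_ref_start is None:
        roi_ref_start = window.roi_start
    roi_offset = roi_ref_start - 1
    if isinstance(groups, dict):
        primaries = [r for g in groups.values() for r in g.primary.values()]
    else:
        primaries = [r for r in groups if r.role == "primary"]
    spans = [(r.ref_start - roi_offset, r.ref_end - roi_offset) for r in primaries]

    clusters: dict[tuple[int, int], list[ITDEvidence]] = {}
    for ev in evidence:
        if ev.method == "softclip_realign":
            pos = _left_align(window, ev.position, ev.length)
        else:
            pos = ev.position
        clusters.setdefault((pos, ev.length), []).append(ev)

    calls: list[ITDCall] = []
    for (pos, length), evs in sorted(clusters.items()):
        sf = len({(e.read_name, e.mate) for e in evs if e.direction == "+"})
        sr = len({(e.read_name, e.mate) for e in evs if e.direction == "-"})
        depth = sum(1 for a, b in spans if a <= max(pos, 1) <= b)
        depth = max(depth, sf + sr)
        method = "softclip_realign"
        if all(e.method == "pair_geometry" for e in evs):
            method = "pair_geometry"
        inserted: str | None = None
        if method == "softclip_realign":
            try:
                inserted = window.slice(pos, pos + length - 1)
            except ValueError:
                inserted = None
        calls.append(
            ITDCall(
                ref_name=window.chrom,
                position=window.roi_start + pos - 1,
                length=length,
                inserted_seq=inserted,
                support_forward=sf,
                support_reverse=sr,
                depth=depth,
                vaf=(sf + sr) / depth,
                method=method,
                low_confidence=all(e.low_confidence for e in evs),
            )
        )
    calls.sort(key=lambda c: (c.position, c.length))
    return calls


def detect_itds(
    alignments,
    window: ReferenceWindow,
    params: CallerParams = CallerParams(),
    region: str | None = None,
    roi_ref_start: int | None = None,
) -> list[ITDCall]:
    """End-to-end detection: SAM/BAM path (or record stream) to sorted calls.

    ``roi_ref_start`` follows :func:`collect_evidence`; when omitted and the
    input is a file whose single contig length equals the stored window
    slice, the windowed-slice convention is assumed, otherwise genomic
    coordinates.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        if roi_ref_start is None:
            roi_ref_start = _guess_roi_ref_start(str(alignments), window)
        stream = read_alignments(alignments, region)
    else:
        stream = alignments
    groups = group_by_read(stream)
    evidence = collect_evidence(groups, window, params, roi_ref_start)
    return aggregate_calls(evidence, groups, window, roi_ref_start)


def _guess_roi_ref_start(path: str, window: ReferenceWindow) -> int:
    slice_len = len(window.left_flank) + len(window) + len(window.right_flank)
    mode = "rb" if path.endswith(".bam") else "r"
    try:
        with pysam.AlignmentFile(path, mode, check_sq=False) as af:
            lens = dict(zip(af.references, af.lengths))
    except (OSError, ValueError):
        return window.roi_start
    if lens.get(window.chrom) == slice_len:
        return len(window.left_flank) + 1
    return window.roi_start
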