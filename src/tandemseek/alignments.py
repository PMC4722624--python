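"""SAM/BAM ingestion: an aligner-agnostic alignment record model.

Parses alignments through pysam into plain records, classifies their role
from the flag bits (primary / secondary / supplementary / unmapped),
extracts terminal soft-clip geometry, and groups records by read name.
Reference positions are 1-based inclusive throughout (SAM convention);
the 0-based pysam layer is confined to this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

from .amplicon import parse_region

__all__ = [
    "AlignedRead",
    "SoftClip",
    "SAEntry",
    "read_alignments",
    "extract_soft_clips",
    "group_by_read",
    "ReadGroup",
]

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class SAEntry:
    """One entry of the SA tag: the realignment of clipped bases elsewhere."""

    ref_name: str
    ref_start: int  # 1-based leftmost
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS) - 1

    @property
    def query_start(self) -> int:
        """1-based first aligned base in the stored read orientation."""
        q = 0
        for op, n in self.cigar:
            if op in "SH":
                q += n
            else:
                break
        return q + 1

    @property
    def query_end(self) -> int:
        q = 0
        end = 0
        for op, n in self.cigar:
            if op in "SH":
                q += n
            elif op in _QUERY_OPS:
                q += n
                end = q
            # D/N consume no query
        return end


@dataclass(frozen=True)
class AlignedRead:
    """One SAM record, aligner-agnostic.

    ``cigar`` is a tuple of ``(operation, length)`` with operations from
    MIDNSHP=X.  ``seq`` may be None (secondary/supplementary records often
    store '*').  ``role`` is one of primary/secondary/supplementary/unmapped.
    """

    name: str
    is_mate1: bool
    strand: str
    role: str
    ref_name: str | None
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: str | None
    mapq: int
    sa: tuple[SAEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("primary", "secondary", "supplementary", "unmapped"):
            raise ValueError(f"bad role {self.role!r}")
        if self.role != "unmapped":
            if self.ref_start < 1:
                raise ValueError("ref_start must be >= 1 for mapped records")
            if self.seq is not None:
                qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
                if qlen != len(self.seq):
                    raise ValueError(
                        f"CIGAR query length {qlen} != sequence length {len(self.seq)} "
                        f"for read {self.name}"
                    )

    @property
    def ref_end(self) -> int:
        """1-based rightmost aligned reference position."""
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS) - 1

    @property
    def query_start(self) -> int:
        q = 0
        for op, n in self.cigar:
            if op in "SH":
                q += n
            else:
                break
        return q + 1

    @property
    def query_end(self) -> int:
        q = 0
        end = 0
        for op, n in self.cigar:
            if op in "SH":
                q += n
            elif op in _QUERY_OPS:
                q += n
                end = q
        return end

    @property
    def mate(self) -> int:
        return 1 if self.is_mate1 else 2


@dataclass(frozen=True)
class SoftClip:
    """A terminal soft clip on a mapped record.

    ``side`` is ``left``/``right`` in reference orientation;
    ``clip_point_ref`` is the aligned base adjacent to the clip (first
    aligned base for left clips, last aligned base for right clips).
    """

    side: str
    clip_point_ref: int
    clip_length: int
    clipped_seq: str | None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if self.clip_length < 1:
            raise ValueError("clip_length must be >= 1")
        if self.clipped_seq is not None and len(self.clipped_seq) != self.clip_length:
            raise ValueError("clipped_seq length != clip_length")


def _parse_sa_tag(value: str) -> tuple[SAEntry, ...]:
    entries = []
    for chunk in value.rstrip(";").split(";"):
        if not chunk:
            continue
        rname, pos, strand, cig, mapq, _nm = chunk.split(",")
        entries.append(
            SAEntry(rname, int(pos), strand, _parse_cigar_string(cig), int(mapq))
        )
    return tuple(entries)


def _parse_cigar_string(cig: str) -> tuple[tuple[str, int], ...]:
    out = []
    n = ""
    for ch in cig:
        if ch.isdigit():
            n += ch
        else:
            out.append((ch, int(n)))
            n = ""
    return tuple(out)


_CIGAR_OPS = "MIDNSHP=X"


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    if rec.is_unmapped:
        role = "unmapped"
    elif rec.is_secondary:
        role = "secondary"
    elif rec.is_supplementary:
        role = "supplementary"
    else:
        role = "primary"
    cig = tuple(
        (_CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or ())
    )
    sa: tuple[SAEntry, ...] = ()
    if rec.has_tag("SA"):
        sa = _parse_sa_tag(rec.get_tag("SA"))
    # mate flags: an unpaired read counts as mate 1
    is_mate1 = (not rec.is_paired) or rec.is_read1
    return AlignedRead(
        name=rec.query_name,
        is_mate1=is_mate1,
        strand="-" if rec.is_reverse else "+",
        role=role,
        ref_name=rec.reference_name,
        ref_start=(rec.reference_start + 1) if not rec.is_unmapped else 0,
        cigar=cig,
        seq=rec.query_sequence,
        mapq=rec.mapping_quality,
        sa=sa,
    )


def read_alignments(path, region: str | None = None) -> Iterator[AlignedRead]:
    """Stream records from SAM/BAM, optionally restricted to a region.

    For indexed BAM the region query uses the index; for SAM (or un-indexed
    BAM) the file is scanned and filtered by overlap.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        if region is None:
            for rec in af:
                yield _from_pysam(rec)
            return
        chrom, start, end = parse_region(region)
        if af.has_index():
            for rec in af.fetch(chrom, start - 1, end):
                yield _from_pysam(rec)
            return
        for rec in af:
            if rec.is_unmapped or rec.reference_name != chrom:
                continue
            if rec.reference_start + 1 > end or rec.reference_end < start:
                continue
            yield _from_pysam(rec)


def extract_soft_clips(read: AlignedRead, min_clip: int = 1) -> list[SoftClip]:
    """Terminal soft clips of length >= ``min_clip`` (hard clips never qualify).

    The clip point of a right clip is ``ref_start`` plus the total
    reference-consuming CIGAR length minus one; of a left clip, ``ref_start``
    itself.
    """
    if read.role == "unmapped":
        raise ValueError("cannot extract clips from an unmapped record")
    if not read.cigar:
        raise ValueError(f"record {read.name} has no CIGAR")
    clips: list[SoftClip] = []
    cig = list(read.cigar)
    # leading hard clip does not appear in seq; adjust offsets for S lookup
    i = 1 if cig[0][0] == "H" else 0
    j = len(cig) - (2 if cig[-1][0] == "H" else 1)
    if i <= j and cig[i][0] == "S" and cig[i][1] >= min_clip:
        n = cig[i][1]
        seq = read.seq[:n] if read.seq else None
        clips.append(SoftClip("left", read.ref_start, n, seq))
    if j >= i and cig[j][0] == "S" and cig[j][1] >= min_clip and j != i:
        n = cig[j][1]
        seq = read.seq[-n:] if read.seq else None
        clips.append(SoftClip("right", read.ref_end, n, seq))
    return clips


@dataclass
class ReadGroup:
    """All records of one read name, split by role and mate."""

    name: str
    primary: dict[int, AlignedRead]
    secondary: list[AlignedRead]

    def primary_of(self, mate: int) -> AlignedRead | None:
        return self.primary.get(mate)


def group_by_read(stream: Iterable[AlignedRead]) -> dict[str, ReadGroup]:
    """Group records by read name; primaries keyed by mate, the rest pooled.

    Every input record lands in exactly one group; unmapped records are
    dropped (they carry no positional evidence).
    """
    groups: dict[str, ReadGroup] = {}
    for rec in stream:
        if rec.role == "unmapped":
            continue
        g = groups.get(rec.name)
        if g is None:
            g = groups[rec.name] = ReadGroup(rec.name, {}, [])
        if rec.role == "primary":
            if rec.mate in g.primary:
                raise ValueError(f"duplicate primary record for {rec.name} mate {rec.mate}")
            g.primary[rec.mate] = rec
        else:
            g.secondary.append(rec)
    return groups
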