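"""Amplicon region of interest: sequence, flanks and coordinate conversions.

The unit of analysis is a single PCR amplicon — a reference window with
1-based inclusive genomic coordinates, its nucleotide sequence, and optional
flanking sequence on either side.  Flanks serve two purposes: they let the
simulator resolve duplicated segments that run past the window end, and they
give the aligner genomic context so that reads extending beyond the window
still align contiguously.

All user-facing coordinates are 1-based inclusive.  Conversion to 0-based
half-open happens only at file and library boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyfaidx import Fasta

__all__ = [
    "ReferenceWindow",
    "parse_region",
    "load_reference_window",
    "synthetic_window",
    "write_alignment_reference",
]

_VALID = re.compile(r"^[ACGTN]*$")

_REGION = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,  ]+)-(?P<end>[\d,  ]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive; thousands separators allowed).

    >>> parse_region("chr13:28,608,112-28,608,312")
    ('chr13', 28608112, 28608312)
    """
    m = _REGION.match(region.strip())
    if not m:
        raise ValueError(f"malformed region string: {region!r} (expected chrom:start-end)")
    clean = lambda s: int(re.sub(r"[,  ]", "", s))
    chrom, start, end = m.group("chrom"), clean(m.group("start")), clean(m.group("end"))
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}: start={start}, end={end}")
    return chrom, start, end


@dataclass(frozen=True)
class ReferenceWindow:
    """A reference region of interest (ROI) with optional flanking sequence.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name of the region.
    roi_start, roi_end : int
        Genomic coordinates of the ROI, 1-based inclusive.
    roi_seq : str
        Uppercase ROI sequence; ``len(roi_seq) == roi_end - roi_start + 1``.
    left_flank, right_flank : str
        Uppercase flanking sequence (possibly empty); ``left_flank`` ends at
        ``roi_start - 1`` and ``right_flank`` begins at ``roi_end + 1``.
    """

    chrom: str
    roi_start: int
    roi_end: int
    roi_seq: str
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if len(self.roi_seq) != self.roi_end - self.roi_start + 1:
            raise ValueError(
                f"ROI length {len(self.roi_seq)} does not match coordinates "
                f"{self.chrom}:{self.roi_start}-{self.roi_end}"
            )
        for name in ("roi_seq", "left_flank", "right_flank"):
            seq = getattr(self, name)
            if not _VALID.match(seq):
                raise ValueError(f"{name} contains characters outside ACGTN")

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return len(self.roi_seq)

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.roi_start}-{self.roi_end}"

    def roi_to_genomic(self, roi_pos: int) -> int:
        """Map a 1-based ROI position onto the genome."""
        if not 1 <= roi_pos <= len(self):
            raise ValueError(f"ROI position {roi_pos} outside 1..{len(self)}")
        return self.roi_start + roi_pos - 1

    def genomic_to_roi(self, genomic_pos: int) -> int:
        """Inverse of :meth:`roi_to_genomic`."""
        if not self.roi_start <= genomic_pos <= self.roi_end:
            raise ValueError(
                f"genomic position {genomic_pos} outside {self.region}"
            )
        return genomic_pos - self.roi_start + 1

    # -- sequence access in extended ROI coordinates --------------------

    def slice(self, start: int, end: int) -> str:
        """ROI-coordinate slice, 1-based inclusive, flanks addressable.

        ``start`` may run below 1 (into the left flank) and ``end`` above the
        ROI length (into the right flank).  Raises if the requested range is
        not covered by the stored flanks.
        """
        if end < start:
            raise ValueError(f"empty slice {start}..{end}")
        lo = start - 1 + len(self.left_flank)
        hi = end + len(self.left_flank)
        whole = self.left_flank + self.roi_seq + self.right_flank
        if lo < 0 or hi > len(whole):
            raise ValueError(
                f"slice {start}..{end} exceeds stored flanks "
                f"(left={len(self.left_flank)} bp, right={len(self.right_flank)} bp)"
            )
        return whole[lo:hi]


def load_reference_window(fasta_path, region: str, flank: int = 0) -> ReferenceWindow:
    """Load a window (plus up to ``flank`` bp of context each side) from FASTA.

    Flanks are truncated silently at the ends of the source sequence.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    chrom, start, end = parse_region(region)
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    if chrom not in fa:
        raise KeyError(f"sequence {chrom!r} not found in {fasta_path}")
    seqlen = len(fa[chrom])
    if end > seqlen:
        raise ValueError(f"region {region} exceeds sequence length {seqlen}")
    roi = str(fa[chrom][start - 1:end])
    lf = str(fa[chrom][max(0, start - 1 - flank):start - 1])
    rf = str(fa[chrom][end:min(seqlen, end + flank)])
    return ReferenceWindow(chrom, start, end, roi, lf, rf)


def synthetic_window(
    roi_length: int = 201,
    flank: int = 400,
    seed: int = 1290,
    chrom: str = "ampliconA",
    roi_start: int = 10001,
) -> ReferenceWindow:
    """Deterministic synthetic reference window (non-repetitive, GC ~ 0.5).

    A stand-in fixture for an amplicon region of interest when no genome
    FASTA is at hand.  The sequence is synthetic: generated from a fixed
    linear-congruential stream so that the same arguments always produce the
    same window, and rejected/regenerated until no 13-mer occurs twice
    (non-repetitiveness keeps soft-clip realignment unambiguous, as in a
    typical single-copy exonic target).
    """
    n = roi_length + 2 * flank

    def gen(s: int) -> str:
        out = []
        x = s & 0x7FFFFFFF
        for _ in range(n):
            x = (1103515245 * x + 12345) & 0x7FFFFFFF
            out.append("ACGT"[(x >> 16) & 3])
        return "".join(out)

    def repetitive(seq: str, k: int = 13) -> bool:
        seen = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if kmer in seen:
                return True
            seen.add(kmer)
        return False

    s = seed
    seq = gen(s)
    while repetitive(seq):
        s += 1
        seq = gen(s)
    return ReferenceWindow(
        chrom,
        roi_start,
        roi_start + roi_length - 1,
        seq[flank:flank + roi_length],
        seq[:flank],
        seq[flank + roi_length:],
    )


def write_alignment_reference(window: ReferenceWindow, fasta_path) -> int:
    """Write ``left_flank + ROI + right_flank`` as one FASTA record.

    The record is named ``window.chrom`` and starts at genomic coordinate
    ``roi_start - len(left_flank)``.  Returns the 1-based position of the ROI
    start within the written contig (needed to translate alignment
    coordinates back to the genome).  Sequence is wrapped at 70 columns.
    """
    seq = window.left_flank + window.roi_seq + window.right_flank
    with open(fasta_path, "w") as fh:
        fh.write(f">{window.chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    return len(window.left_flank) + 1
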