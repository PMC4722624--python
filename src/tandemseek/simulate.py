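"""Exhaustive internal-tandem-duplication (ITD) read simulator.

Builds mutant alleles over a reference window and writes error-free
paired-end amplicon reads at a chosen allelic burden.  The simulator is the
ground-truth generator for characterising a caller's detection envelope: the
full Cartesian grid of duplication start positions (1..ROI length) and
lengths (1..max length) can be enumerated, simulated and scored.

Allele construction
-------------------
An ITD duplicates the reference segment of ``length_L`` bases beginning at
ROI position ``start_p`` and inserts the copy immediately after the original.
The simulated amplicon insert is the first ``ROI + L`` bases of that mutant
chromosome starting at the ROI start::

    allele = R[1 .. p+L-1] + ROI[p .. ROI_len]

where ``R`` is the ROI extended by its right flank.  For segments lying
inside the ROI this is the familiar tandem repeat
``ROI[1..p+L-1] + ROI[p..p+L-1] + ROI[p+L..]``; for segments running past
the ROI end, the first copy is completed from flanking sequence and the
trailing copy is truncated at the amplicon boundary, exactly as a fixed-size
amplicon of the mutant genome would be.  Allele length is ``ROI + L`` at
every grid point.

Read model
----------
Reads are error-free with fixed start positions (amplicon chemistry: every
fragment begins and ends at the oligo boundaries).  Mate 1 is the leading
bases of the insert, mate 2 the reverse complement of its trailing bases.
When the insert is shorter than the read length, the sequencer reads through
into the library adapter; pass ``adapter1``/``adapter2`` (or use the
:data:`READTHROUGH_ADAPTER_R1`/`R2` defaults via
:func:`simulate_combination`) to emulate that.  With no adapter the read is
simply truncated at the insert end.  There is no randomness anywhere:
identical inputs give byte-identical FASTQ.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .amplicon import ReferenceWindow

__all__ = [
    "ITDSpec",
    "SimulatedPair",
    "READTHROUGH_ADAPTER_R1",
    "READTHROUGH_ADAPTER_R2",
    "revcomp",
    "build_itd_allele",
    "simulate_pairs_from_template",
    "simulate_combination",
    "enumerate_grid",
    "write_truth_table",
]

#: Illumina TruSeq universal adapter read-through, as seen at the 3' end of a
#: read whose insert is shorter than the read length (index + flow-cell tail
#: padded so any read length up to 275 bp is covered).
READTHROUGH_ADAPTER_R1 = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"
    + "A" * 40
)
READTHROUGH_ADAPTER_R2 = (
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"
    + "A" * 40
)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ITDSpec:
    """One simulated tandem-duplication allele.

    ``start_p`` and ``length_L`` are the 1-based ROI position of the first
    duplicated base and the duplication length in bp.  ``allelic_burden`` is
    the fraction of read pairs carrying the ITD allele; the remainder are
    wild type.
    """

    start_p: int
    length_L: int
    allelic_burden: float = 0.5
    n_pairs_total: int = 2000
    read_length: int = 275
    base_quality: int = 30

    def __post_init__(self) -> None:
        if self.start_p < 1:
            raise ValueError("start_p must be >= 1")
        if self.length_L < 1:
            raise ValueError("length_L must be >= 1")
        if not 0.0 <= self.allelic_burden <= 1.0:
            raise ValueError("allelic_burden must lie in [0, 1]")
        if self.n_pairs_total < 1:
            raise ValueError("n_pairs_total must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")

    @property
    def combination_id(self) -> str:
        return f"c{self.start_p}_{self.length_L}"

    @staticmethod
    def parse_combination_id(cid: str) -> tuple[int, int]:
        m = re.match(r"^c(\d+)_(\d+)$", cid)
        if not m:
            raise ValueError(f"not a combination id: {cid!r}")
        return int(m.group(1)), int(m.group(2))

    @property
    def n_itd_pairs(self) -> int:
        """Round-half-up of burden x total, floored at 1 whenever burden > 0."""
        n = int(math.floor(self.n_pairs_total * self.allelic_burden + 0.5))
        if self.allelic_burden > 0:
            n = max(n, 1)
        return min(n, self.n_pairs_total)

    @property
    def n_wt_pairs(self) -> int:
        return self.n_pairs_total - self.n_itd_pairs


@dataclass(frozen=True)
class SimulatedPair:
    read_name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    truth: ITDSpec | None = None  # None marks a wild-type pair

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


def build_itd_allele(window: ReferenceWindow, start_p: int, length_L: int) -> str:
    """Mutant amplicon insert for a duplication of ``length_L`` bp at ``start_p``.

    Raises if the duplicated segment cannot be resolved from the stored right
    flank, or contains N (ambiguous reads are refused rather than emitted).
    """
    n = len(window)
    if not 1 <= start_p <= n:
        raise ValueError(f"start_p {start_p} outside ROI 1..{n}")
    if length_L < 1:
        raise ValueError("length_L must be >= 1")
    seg_end = start_p + length_L - 1
    if seg_end > n + len(window.right_flank):
        raise ValueError(
            f"duplicated segment {start_p}..{seg_end} extends {seg_end - n} bp past "
            f"the ROI end but only {len(window.right_flank)} bp of right flank are stored"
        )
    segment = window.slice(start_p, seg_end)
    if "N" in segment:
        raise ValueError(
            f"duplicated segment {start_p}..{seg_end} contains N; refusing to simulate"
        )
    allele = window.slice(1, seg_end) + window.roi_seq[start_p - 1:]
    assert len(allele) == n + length_L
    return allele


def simulate_pairs_from_template(
    template: str,
    n_pairs: int,
    read_length: int = 275,
    base_quality: int = 30,
    adapter1: str | None = None,
    adapter2: str | None = None,
    name_prefix: str = "pair",
    truth: ITDSpec | None = None,
) -> list[SimulatedPair]:
    """Error-free identical read pairs from one template (fixed-start amplicon).

    Mate 1 is the first ``min(read_length, len(template))`` template bases;
    mate 2 is the reverse complement of the last ones.  With ``adapter1``/
    ``adapter2`` given, short templates read through into adapter up to the
    full read length instead of truncating.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not template:
        raise ValueError("template must be non-empty")
    t1 = template + (adapter1 or "")
    t2 = revcomp(template) + (adapter2 or "")
    seq1 = t1[:read_length]
    seq2 = t2[:read_length]
    q = chr(base_quality + 33)
    qual1, qual2 = q * len(seq1), q * len(seq2)
    return [
        SimulatedPair(f"{name_prefix}:{i}", seq1, qual1, seq2, qual2, truth)
        for i in range(n_pairs)
    ]


def _open_maybe_gz(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def simulate_combination(
    window: ReferenceWindow,
    spec: ITDSpec,
    fastq1,
    fastq2,
    adapter_readthrough: bool = True,
    _handles=None,
) -> dict:
    """Simulate one (start, length, burden) combination to a FASTQ pair.

    Writes ``round(n_pairs_total x burden)`` ITD pairs (floored at one pair
    for any burden > 0) followed by wild-type pairs, and returns the truth
    record used for downstream scoring.  Read names encode the allele of
    origin as ``<combination_id>:<itd|wt>:<index>`` so pooled runs can be
    demultiplexed after alignment.
    """
    a1 = READTHROUGH_ADAPTER_R1 if adapter_readthrough else None
    a2 = READTHROUGH_ADAPTER_R2 if adapter_readthrough else None
    cid = spec.combination_id
    itd_pairs: list[SimulatedPair] = []
    if spec.n_itd_pairs:
        allele = build_itd_allele(window, spec.start_p, spec.length_L)
        itd_pairs = simulate_pairs_from_template(
            allele, spec.n_itd_pairs, spec.read_length, spec.base_quality,
            a1, a2, f"{cid}:itd", spec,
        )
    wt_pairs: list[SimulatedPair] = []
    if spec.n_wt_pairs:
        wt_pairs = simulate_pairs_from_template(
            window.roi_seq, spec.n_wt_pairs, spec.read_length, spec.base_quality,
            a1, a2, f"{cid}:wt", None,
        )

    if _handles is not None:
        fh1, fh2 = _handles
        _write_fastq(fh1, fh2, itd_pairs + wt_pairs)
    else:
        with _open_maybe_gz(fastq1) as fh1, _open_maybe_gz(fastq2) as fh2:
            _write_fastq(fh1, fh2, itd_pairs + wt_pairs)

    return {
        "combination_id": cid,
        "start_p": spec.start_p,
        "length_L": spec.length_L,
        "burden": spec.allelic_burden,
        "n_itd_pairs": spec.n_itd_pairs,
        "n_wt_pairs": spec.n_wt_pairs,
    }


def _write_fastq(fh1, fh2, pairs: Iterable[SimulatedPair]) -> None:
    for p in pairs:
        fh1.write(f"@{p.read_name}\n{p.seq1}\n+\n{p.qual1}\n")
        fh2.write(f"@{p.read_name}\n{p.seq2}\n+\n{p.qual2}\n")


def enumerate_grid(
    window: ReferenceWindow,
    max_length: int | None = None,
    burden: float = 0.5,
    n_pairs_total: int = 2000,
    read_length: int = 275,
    start_step: int = 1,
    length_step: int = 1,
) -> list[ITDSpec]:
    """Full Cartesian product of start positions and lengths, row-major.

    Defaults reproduce the exhaustive grid over a 201 bp window: 201 starts x
    201 lengths = 40,401 combinations at 50 % burden.  ``start_step`` /
    ``length_step`` thin the grid for quick runs.
    """
    if max_length is None:
        max_length = len(window)
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return [
        ITDSpec(p, L, burden, n_pairs_total, read_length)
        for p in range(1, len(window) + 1, start_step)
        for L in range(1, max_length + 1, length_step)
    ]


def write_truth_table(records: Sequence[dict], path) -> None:
    """Tab-separated truth table: one row per simulated combination."""
    cols = ["combination_id", "start_p", "length_L", "burden", "n_itd_pairs", "n_wt_pairs"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
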