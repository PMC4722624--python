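"""VCF serialization of ITD calls and clinical reporting-policy labels.

Calls are annotated, never suppressed: the reporting policy (minimum VAF,
minimum depth) becomes FILTER labels so that sub-threshold signal stays
inspectable.  Output is VCF 4.2; records carry the duplicated sequence as an
explicit insertion allele when it is resolvable from the reference window,
and a symbolic ``<DUP:TANDEM>`` allele with SVLEN otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .amplicon import ReferenceWindow
from .caller import ITDCall

__all__ = ["ReportingPolicy", "apply_policy", "calls_to_vcf"]


@dataclass(frozen=True)
class ReportingPolicy:
    """Clinical reportability thresholds (both inclusive).

    Defaults: minimum reportable variant allele fraction 10 % at a minimum
    sequencing depth of 500-fold; shallower positions are flagged as
    sub-optimally covered rather than dropped.
    """

    min_vaf: float = 0.10
    min_depth: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def apply_policy(
    calls: Sequence[ITDCall], policy: ReportingPolicy = ReportingPolicy()
) -> list[tuple[ITDCall, list[str]]]:
    """Annotate each call with its FILTER labels (pure; drops nothing).

    Returns ``(call, labels)`` pairs where ``labels`` is ``["PASS"]`` or any
    of ``LowVAF`` (vaf < min_vaf) and ``LowDepth`` (depth < min_depth).
    """
    out = []
    for call in calls:
        labels: list[str] = []
        if call.vaf < policy.min_vaf:
            labels.append("LowVAF")
        if call.depth < policy.min_depth:
            labels.append("LowDepth")
        out.append((call, labels or ["PASS"]))
    return out


_HEADER = """\
##fileformat=VCFv4.2
##source=tandemseek
##reference={ref}
##contig=<ID={chrom}>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the tandem duplication in bp">
##INFO=<ID=SF,Number=1,Type=Integer,Description="Supporting reads, forward direction">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Supporting reads, reverse direction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the call position">
##INFO=<ID=METHOD,Number=1,Type=String,Description="Evidence type: softclip_realign or pair_geometry">
##INFO=<ID=LOWCONF,Number=0,Type=Flag,Description="Single-mate pure-insertion inference">
##FILTER=<ID=LowVAF,Description="Variant allele fraction below {min_vaf:g} (inclusive threshold)">
##FILTER=<ID=LowDepth,Description="Depth below {min_depth}-fold (inclusive threshold)">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction (support/depth)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at the call position">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def calls_to_vcf(
    calls: Sequence[ITDCall],
    window: ReferenceWindow,
    policy: ReportingPolicy = ReportingPolicy(),
    out=None,
    sample: str = "SAMPLE",
) -> str:
    """Serialize calls to VCF 4.2 text; optionally write to ``out`` path.

    One record per call, REF = reference base at the (left-aligned) call
    position, ALT = REF followed by the duplicate copy when resolvable.
    """
    lines = [
        _HEADER.format(
            ref=window.region,
            chrom=window.chrom,
            min_vaf=policy.min_vaf,
            min_depth=policy.min_depth,
            sample=sample,
        )
    ]
    for call, labels in apply_policy(calls, policy):
        roi_pos = call.position - window.roi_start + 1
        try:
            ref_base = window.slice(roi_pos, roi_pos)
        except ValueError as exc:
            raise ValueError(
                f"call position {call.position} outside window {window.region}"
            ) from exc
        if call.inserted_seq is not None:
            alt = ref_base + call.inserted_seq
        else:
            alt = "<DUP:TANDEM>"
        info = (
            f"SVTYPE=DUP;SVLEN={call.length};SF={call.support_forward};"
            f"SR={call.support_reverse};DP={call.depth};METHOD={call.method}"
        )
        if call.low_confidence:
            info += ";LOWCONF"
        lines.append(
            "\t".join(
                [
                    call.ref_name,
                    str(call.position),
                    ".",
                    ref_base,
                    alt,
                    ".",
                    ";".join(labels),
                    info,
                    "AF:DP",
                    f"{call.vaf:.6g}:{call.depth}",
                ]
            )
            + "\n"
        )
    text = "".join(lines)
    if out is not None:
        with open(out, "w") as fh:
            fh.write(text)
    return text
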