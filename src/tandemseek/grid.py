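"""Detection-envelope evaluation over the exhaustive (start x length) grid.

Simulates every requested duplication combination, aligns the pooled reads
with an external soft-clipping aligner (default: ``bwa mem`` with default
parameters), runs the caller, and scores each combination as detected or
not.  Because the simulated reads are error-free with fixed start positions,
all pairs of one combination are identical: per-combination read counts can
be reduced far below sequencing depth, and many combinations can share one
alignment batch (demultiplexed afterwards by read name) without changing
any outcome.

A combination (p, L) counts as detected iff some call has exactly length L
and a position within ``[p - L, p + L]`` — length must be exact, the
position window absorbs repeat-induced coordinate ambiguity.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import ReferenceWindow, write_alignment_reference
from .alignments import group_by_read, read_alignments
from .caller import CallerParams, aggregate_calls, collect_evidence, ITDCall
from .simulate import ITDSpec, simulate_combination

__all__ = [
    "DetectionGrid",
    "GridSummary",
    "DEFAULT_ALIGNER",
    "score_combination",
    "run_grid",
    "summarize_grid",
]

DEFAULT_ALIGNER = "bwa mem {reference_fasta} {fastq1} {fastq2}"


@dataclass
class DetectionGrid:
    """Detected/undetected matrix over (start position, duplication length)."""

    starts: list[int]
    lengths: list[int]
    detected: np.ndarray  # bool, shape (len(starts), len(lengths))
    metadata: dict = field(default_factory=dict)
    calls: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.detected.shape != (len(self.starts), len(self.lengths)):
            raise ValueError("detection matrix shape does not match axes")

    def rate(self) -> float:
        return float(self.detected.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, L, bool(self.detected[i, j]))
            for i, p in enumerate(self.starts)
            for j, L in enumerate(self.lengths)
        ]
        return pd.DataFrame(rows, columns=["start_p", "length_L", "detected"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DetectionGrid":
        df = pd.read_csv(path, sep="\t")
        starts = sorted(df["start_p"].unique())
        lengths = sorted(df["length_L"].unique())
        mat = np.zeros((len(starts), len(lengths)), dtype=bool)
        si = {p: i for i, p in enumerate(starts)}
        li = {L: j for j, L in enumerate(lengths)}
        for p, L, d in df.itertuples(index=False):
            mat[si[p], li[L]] = bool(d)
        return cls([int(p) for p in starts], [int(L) for L in lengths], mat)


@dataclass
class GridSummary:
    """Summary statistics of a detection grid."""

    detection_rate: float
    n_detected: int
    n_total: int
    min_detected_length: dict[int, int | None]
    max_detected_length: dict[int, int | None]
    insensitive_positions: list[int]

    @property
    def floor_min(self) -> int | None:
        vals = [v for v in self.min_detected_length.values() if v is not None]
        return min(vals) if vals else None

    @property
    def floor_max(self) -> int | None:
        vals = [v for v in self.min_detected_length.values() if v is not None]
        return max(vals) if vals else None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"overall_detection_rate\t{self.detection_rate:.6f}\n")
            fh.write(f"n_detected\t{self.n_detected}\n")
            fh.write(f"n_total\t{self.n_total}\n")
            fh.write(f"n_insensitive_positions\t{len(self.insensitive_positions)}\n")
            fh.write(
                "insensitive_positions\t"
                + ",".join(map(str, self.insensitive_positions))
                + "\n"
            )
            fh.write(f"min_of_position_minima\t{self.floor_min}\n")
            fh.write(f"max_of_position_minima\t{self.floor_max}\n")
        per_pos = Path(str(path)).with_suffix(".per_position.tsv")
        with open(per_pos, "w") as fh:
            fh.write("start_p\tmin_detected_length\tmax_detected_length\n")
            for p in self.min_detected_length:
                lo = self.min_detected_length[p]
                hi = self.max_detected_length[p]
                fh.write(f"{p}\t{'' if lo is None else lo}\t{'' if hi is None else hi}\n")


def score_combination(
    truth: ITDSpec, calls: Sequence[ITDCall], window: ReferenceWindow
) -> bool:
    """Detected iff a call matches the truth: exact length, position within
    ``[p - L, p + L]`` (repeat-ambiguity window)."""
    p, L = truth.start_p, truth.length_L
    for call in calls:
        roi_pos = call.position - window.roi_start + 1
        if call.length == L and p - L <= roi_pos <= p + L:
            return True
    return False


def aligner_version(aligner_command: str = DEFAULT_ALIGNER) -> str:
    """Best-effort version string of the first word of the aligner command."""
    prog = shlex.split(aligner_command)[0]
    try:
        proc = subprocess.run(
            [prog], capture_output=True, text=True, timeout=30
        )
        for line in (proc.stderr + proc.stdout).splitlines():
            if "version" in line.lower():
                return f"{prog} {line.strip()}"
    except (OSError, subprocess.TimeoutExpired):
        pass
    return f"{prog} (version unknown)"


def _align_batch(
    aligner_command: str, reference_fasta: Path, fq1: Path, fq2: Path, sam_out: Path
) -> None:
    cmd = shlex.split(
        aligner_command.format(
            reference_fasta=str(reference_fasta), fastq1=str(fq1), fastq2=str(fq2)
        )
    )
    with open(sam_out, "w") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"aligner failed (exit {proc.returncode}): {' '.join(cmd)}\n{proc.stderr[-2000:]}"
        )


def _ensure_bwa_index(reference_fasta: Path) -> None:
    if not Path(str(reference_fasta) + ".bwt").exists():
        proc = subprocess.run(
            ["bwa", "index", str(reference_fasta)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(f"bwa index failed: {proc.stderr[-2000:]}")


def run_grid(
    window: ReferenceWindow,
    aligner_command: str = DEFAULT_ALIGNER,
    reads_per_combination: int = 4,
    pool_size: int = 500,
    read_length: int = 275,
    burden: float = 0.5,
    max_length: int | None = None,
    start_step: int = 1,
    length_step: int = 1,
    params: CallerParams = CallerParams(),
    workdir=None,
    specs: Sequence[ITDSpec] | None = None,
) -> DetectionGrid:
    """Simulate, align and score a (start x length) grid.

    ``reads_per_combination`` is the number of ITD pairs (an equal number of
    wild-type pairs is added when ``burden`` is 0.5).  Combinations are
    pooled into batches of ``pool_size`` per aligner invocation and
    demultiplexed by read name; per-combination outcomes are unaffected
    because reads are error-free and combination-tagged.
    """
    if specs is None:
        n_total = max(1, round(reads_per_combination / burden)) if burden > 0 else reads_per_combination
        specs = [
            ITDSpec(p, L, burden, n_total, read_length)
            for p in range(1, len(window) + 1, start_step)
            for L in range(
                1, (max_length or len(window)) + 1, length_step
            )
        ]
    starts = sorted({s.start_p for s in specs})
    lengths = sorted({s.length_L for s in specs})
    si = {p: i for i, p in enumerate(starts)}
    li = {L: j for j, L in enumerate(lengths)}
    detected = np.zeros((len(starts), len(lengths)), dtype=bool)
    all_calls: dict[str, list[tuple[int, int]]] = {}

    own_tmp = workdir is None
    tmp = Path(tempfile.mkdtemp(prefix="tandemseek_grid_")) if own_tmp else Path(workdir)
    tmp.mkdir(parents=True, exist_ok=True)
    ref_fa = tmp / "reference.fa"
    roi_ref_start = write_alignment_reference(window, ref_fa)
    if aligner_command.startswith("bwa "):
        _ensure_bwa_index(ref_fa)

    scored = 0
    try:
        for b0 in range(0, len(specs), pool_size):
            batch = specs[b0:b0 + pool_size]
            fq1, fq2 = tmp / "batch_R1.fastq", tmp / "batch_R2.fastq"
            with open(fq1, "w") as h1, open(fq2, "w") as h2:
                for spec in batch:
                    simulate_combination(
                        window, spec, None, None, adapter_readthrough=True,
                        _handles=(h1, h2),
                    )
            sam = tmp / "batch.sam"
            _align_batch(aligner_command, ref_fa, fq1, fq2, sam)
            groups = group_by_read(read_alignments(sam))
            by_combo: dict[str, dict] = {}
            for name, g in groups.items():
                cid = name.split(":", 1)[0]
                by_combo.setdefault(cid, {})[name] = g
            for spec in batch:
                combo_groups = by_combo.get(spec.combination_id, {})
                evidence = collect_evidence(combo_groups, window, params, roi_ref_start)
                calls = aggregate_calls(evidence, combo_groups, window, roi_ref_start)
                ok = score_combination(spec, calls, window)
                detected[si[spec.start_p], li[spec.length_L]] = ok
                all_calls[spec.combination_id] = [
                    (c.position - window.roi_start + 1, c.length) for c in calls
                ]
                scored += 1
        if scored != len(specs):
            raise RuntimeError(
                f"grid incomplete: scored {scored} of {len(specs)} combinations"
            )
    finally:
        if own_tmp:
            import shutil

            shutil.rmtree(tmp, ignore_errors=True)

    meta = {
        "aligner": aligner_version(aligner_command),
        "aligner_command": aligner_command,
        "reads_per_combination": reads_per_combination,
        "read_length": read_length,
        "burden": burden,
        "pool_size": pool_size,
        "n_combinations": len(specs),
    }
    return DetectionGrid(list(starts), list(lengths), detected, meta, all_calls)


def summarize_grid(grid: DetectionGrid) -> GridSummary:
    """Overall rate, per-position extremal detected lengths, blind spots."""
    mins: dict[int, int | None] = {}
    maxs: dict[int, int | None] = {}
    insensitive = []
    lengths = np.asarray(grid.lengths)
    for i, p in enumerate(grid.starts):
        row = grid.detected[i]
        if row.any():
            mins[p] = int(lengths[row].min())
            maxs[p] = int(lengths[row].max())
        else:
            mins[p] = maxs[p] = None
            insensitive.append(p)
    n_det = int(grid.detected.sum())
    return GridSummary(
        detection_rate=grid.rate(),
        n_detected=n_det,
        n_total=int(grid.detected.size),
        min_detected_length=mins,
        max_detected_length=maxs,
        insensitive_positions=insensitive,
    )


def plot_detection_map(grid: DetectionGrid, path) -> None:
    """Optional heat-map rendering of the detection envelope (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        grid.detected.T,
        origin="lower",
        aspect="auto",
        cmap="Reds",
        extent=(grid.starts[0], grid.starts[-1], grid.lengths[0], grid.lengths[-1]),
    )
    ax.set_xlabel("ITD start position in ROI (bp)")
    ax.set_ylabel("ITD length (bp)")
    ax.set_title(f"detected {grid.rate():.1%}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
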