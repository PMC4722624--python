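"""Shared fixtures: synthetic reference window, aligned fixtures, full grid.

Everything is generated programmatically; the only external dependency is
the ``bwa``/``samtools`` pair on PATH for alignment-backed tests.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path

import pysam
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tandemseek import (
    CallerParams,
    ITDSpec,
    ReferenceWindow,
    detect_itds,
    run_grid,
    simulate_combination,
    summarize_grid,
    synthetic_window,
    write_alignment_reference,
)


@pytest.fixture(scope="session")
def window() -> ReferenceWindow:
    return synthetic_window()


@pytest.fixture(scope="session")
def indexed_reference(window, tmp_path_factory) -> tuple[Path, int]:
    """bwa-indexed FASTA of the window slice; returns (path, roi_ref_start)."""
    d = tmp_path_factory.mktemp("ref")
    fa = d / "reference.fa"
    roi_ref_start = write_alignment_reference(window, fa)
    subprocess.run(["bwa", "index", str(fa)], check=True, capture_output=True)
    return fa, roi_ref_start


def align_combination(
    window,
    indexed_reference,
    tmp_path,
    spec: ITDSpec,
    to_bam: bool = False,
):
    """Simulate one combination and align it; returns the SAM/BAM path."""
    fa, _ = indexed_reference
    fq1, fq2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    simulate_combination(window, spec, fq1, fq2)
    sam = tmp_path / "aln.sam"
    with open(sam, "w") as out:
        subprocess.run(
            ["bwa", "mem", str(fa), str(fq1), str(fq2)],
            stdout=out, stderr=subprocess.DEVNULL, check=True,
        )
    if not to_bam:
        return sam
    bam = tmp_path / "aln.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


@pytest.fixture(scope="session")
def full_grid(window):
    """The exhaustive 201x201 detection grid (one shared run; ~1-2 min)."""
    grid = run_grid(window)
    return grid, summarize_grid(grid)
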