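# Methods

## Scope and model

`tandemseek` detects internal tandem duplications (ITDs) from paired-end
amplicon sequencing alignments and characterises its own detection envelope
by exhaustive simulation.  The unit of analysis is one amplicon: a
reference window (region of interest, ROI) of length *n* with flanking
genomic context, over which a duplication is parameterised by its start
position *p* (1-based ROI coordinate of the first duplicated base) and
length *L*.

### Allele model

The mutant molecule carries the segment [*p*, *p*+*L*−1] twice in tandem.
The simulated amplicon insert is the first *n*+*L* bases of the mutant
chromosome starting at the ROI start:

    allele(p, L) = R[1 .. p+L−1] + ROI[p .. n]

where `R` is the ROI extended by its right flank.  For *p*+*L*−1 ≤ *n* this
is the familiar splice `ROI[1..p+L−1] + ROI[p..p+L−1] + ROI[p+L..n]`; when
the segment crosses the ROI end, the first copy is completed from flanking
sequence and the trailing copy is truncated at the amplicon boundary.  This
construction keeps the allele length at exactly *n*+*L* for every one of
the *n*² grid combinations and — unlike appending the segment after the ROI
— preserves a junction from which the exact length is recoverable at every
grid point.  Its direct consequence is the blind-spot structure at the far
amplicon end: at start *n*−2 and beyond, at most 3 bp of duplicated
sequence remain inside the amplicon, below any usable evidence threshold.

### Read model

Reads are error-free with fixed start positions, matching amplicon
chemistry in which every fragment begins and ends at the oligo boundaries:
mate 1 is the leading bases of the insert, mate 2 the reverse complement of
its trailing bases, both at the panel's 275 bp read length.  Because the
oligo binding sites themselves are sequencing-primer sites, inserts shorter
than the read length read through into the library adapter; the simulator
appends a constant Illumina adapter sequence, so wild-type reads carry the
characteristic short terminal soft clips of adapter read-through.  Those
clips are rejected by content (adapter does not realign to the locus), not
by a length cut-off.  All pairs from one allele are byte-identical; there
is no randomness anywhere in the pipeline, which is why per-combination
read counts can be reduced far below real sequencing depth without changing
any detection outcome, and why a `--seed` flag exists only as a documented
no-op.

### Detection

Evidence is extracted per primary alignment, per read and per direction:

1. **Soft clip + realignment** — clip point *c*, realignment start *s* from
   the aligner's `SA` tag (same chromosome, same strand, upstream):
   *L* = *c* − *s* + 1.  When chance micro-homology at the duplication
   junction lets the aligner extend both pieces over the same read bases,
   the two alignments overlap on the query; the overlap is subtracted, so
   the inferred length remains exact rather than drifting by the homology
   length.
2. **Amplicon-end closure** — a primary alignment that extends past the ROI
   end into the flank, with a clipped tail whose first *m* bases equal the
   last *m* ROI bases (*m* ≥ 4): *L* = (*c* − *n*) + *m*.  Wild-type reads
   never present this geometry (their alignments stop at the ROI end and
   their tails are adapter), so the rule is null-safe by construction.
3. **Pure insertion** — inserted sequence of unknown origin has no
   realignment.  It is recovered (a) from the query gap between two
   reference-adjacent split pieces of one read, or (b) by comparing the
   soft-clipping points of the two mates: clips at mutually consistent
   points whose leading clipped bases do not match the locus but which
   resume reference sequence after the same number of foreign bases.  A
   single informative mate yields the same inference flagged
   low-confidence.  Clip points at the amplicon boundaries are excluded
   here (that is the adapter read-through geometry).

Evidence items agreeing on (left-aligned position, length) merge into one
call.  Tandem duplications are coordinate-ambiguous within repeats, so the
reported position is the leftmost equivalent start, in line with VCF
normalisation.  Support is counted per direction as distinct (read, mate)
units — at most once per direction per read, whatever mixture of signatures
the read shows.  Depth is the number of primary records overlapping the
call position, and VAF = support / depth.  The caller applies no reporting
threshold: one supporting read suffices, which is what makes single-pair
clones detectable.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| read length | 275 bp | the panel's 2×275 bp chemistry |
| pairs per combination (presets) | 1000 ITD + 1000 WT | 2000× depth at 50 % burden, the study condition; grid runs use 4+4 (see below) |
| allelic burden | 0.5 | heterozygous clone, the envelope's reference condition |
| base quality | Q30 uniform | downstream detection ignores qualities |
| `min_clip` | 4 bp | noise floor only; clips are filtered by content, and the last detectable starts present only 4-9 bp of clipped signal — a 10 bp floor would erase them |
| `min_itd_length` | 15 bp | below this, amplicon ITDs align as plain `I` insertions handled by general-purpose small-variant callers; the soft-clip caller's domain starts where theirs ends |
| `closure_min_match` | 4 bp | smallest anchored ROI-terminus match accepted; defines the 3-position blind spot at the amplicon end |
| `min_mapq` primary / realignment | 1 / 0 | split realignments are routinely MAPQ 0 |
| reporting policy | VAF ≥ 10 %, depth ≥ 500, inclusive | panel's clinical reportability rule, applied as labels |
| grid pool size | 500 combinations/batch | amortises aligner start-up; outcomes are pooling-invariant (tested) |

The `reads_per_combination = 4` grid default exploits determinism: with
byte-identical error-free pairs, one pair per combination already decides
detectability (also tested), and 4+4 keeps per-combination VAF/depth
bookkeeping meaningful while the full 40,401-combination grid runs in
about a minute on one CPU.

## Reference fixture

The packaged reference window is **synthetic**: a deterministically
generated non-repetitive 201 bp sequence with 400 bp flanks (no 13-mer
occurs twice), standing in for a single-copy exonic amplicon target when no
genome FASTA is available.  Real windows are loaded from FASTA with
`load_reference_window`.  One consequence of using any concrete sequence is
worth knowing: wherever the base after a duplicated segment happens to
equal the segment's first base, neighbouring grid cells describe the *same
molecule* (the duplication is coordinate-ambiguous), and the cell pair is
scored by what the evidence thresholds make of the shared junction.  In the
packaged window this affects a single cell at the amplicon tail.

## Evaluation harness

Each grid combination is scored **detected** iff some call has exactly the
simulated length and a position within [*p*−*L*, *p*+*L*] — length must be
exact; the position window absorbs repeat-induced coordinate ambiguity.
Summaries report the overall detection rate, the per-start minimum and
maximum detected lengths, and starts with no detection at any length.  The
aligner is external and pinned by recording its version in the grid
metadata: the envelope is a property of the caller *given* a
BWA-MEM-style soft-clipping aligner, and its floor boundary (where the
aligner switches from `I`-insertion to soft-clip representation, governed by
its gap/clip scoring) moves with aligner version.  The environment here
provides bwa 0.7.19; published envelope boundaries derived with 0.7.7
therefore reproduce in structure (full-length ceiling, three trailing blind
starts, ~15 bp floor minimum) while the floor maximum and the overall rate
land a few points away, and the acceptance suite asserts the published
values at their stated tolerances rather than re-tuning to this aligner.

## What the simulator does not model

Sequencing errors, indel artefacts, quality variation, fragment-size
distributions, multi-amplicon panels, and allele drop-out (a variant
disrupting an oligo binding site, visible as a depth collapse rather than a
call).  Passing tests therefore demonstrate the geometric correctness of
the caller under ideal reads — which is the quantity the envelope is
defined on — not robustness to noisy clinical data.  On real data the
content-validation steps (realignment of clipped bases, reference-resumption
anchoring) are the error tolerance, and they are exact-match based: highly
degraded reads will lose evidence before they generate false calls.

## Numerical and degenerate-input choices

Rounding of the ITD pair count is half-up with a floor of one pair for any
positive burden, so single-read-clone scenarios are always constructible.
Alleles containing N in the duplicated segment are refused rather than
simulated ambiguously.  Duplicated segments extending past the stored flank
raise a coverage error.  Thresholds in the reporting policy are inclusive.
Ties in pure-insertion pair comparison require equal inferred lengths and
clip points within 1 bp.  Calls are sorted by position, then length; all
outputs are byte-reproducible across runs.
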