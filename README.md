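# tandemseek

Soft-clip based detection of *FLT3* internal tandem duplications (ITDs) from
amplicon next-generation sequencing, together with an exhaustive error-free
ITD read simulator and a detection-envelope evaluation harness.

## The problem

*FLT3*-ITD is a recurrent, prognostically adverse mutation in acute myeloid
leukemia: an in-frame duplication of 15–200+ bp inserted in tandem next to
its template in exons 13–15.  Short ITDs in the middle of a read align as a
plain CIGAR insertion (`I`) and are caught by general-purpose variant
callers.  But when the duplication is long, or sits close to an amplicon
end, the duplicated bases are **soft-clipped** (`S`) instead — and
soft-clipped bases are exactly what general-purpose callers ignore, as if
they were sequencing adapter.  On amplicon panels this blind spot covers
most of the clinically relevant ITD spectrum.

`tandemseek` closes it by reading the signal the aligner already produces:

1. **Soft clip + realignment.**  A split-read aligner (BWA-MEM) realigns
   clipped bases to the same locus and records the realignment as a
   supplementary alignment (`SA` tag).  For a clip point *c* (last aligned
   base before a right clip) whose clipped bases realign starting at
   *s* ≤ *c*, the duplication spans [*s*, *c*] and its length is

   &nbsp;&nbsp;&nbsp;&nbsp;**L = c − s + 1**

   with a query-overlap correction when chance junction micro-homology lets
   the aligner extend both pieces over the same read bases.
2. **Amplicon-end closure.**  A duplication whose first copy runs past the
   region of interest (ROI) leaves a primary alignment extending into the
   flank plus a clipped tail equal to the ROI terminus; matching the clip
   against the terminus closes the amplicon geometry and fixes L exactly.
3. **Pure insertions** of unknown origin (no realignment anywhere) are
   recovered from the query gap between adjacent split pieces, or by
   comparing the soft-clipping points of the two mates of a pair.

Analysis is per read and per direction, so a clone supported by a single
read pair is still called, and multiple co-existing clones yield multiple
calls.  Calls are reported in VCF 4.2 with support per direction, depth and
variant allele fraction (VAF = support/depth); the clinical reporting policy
(minimum 10 % VAF at ≥ 500-fold depth, both inclusive) is applied as
`LowVAF`/`LowDepth` FILTER labels — sub-threshold signal is labelled, never
dropped.

## Worked example

Simulate a 60 bp duplication starting at ROI position 150 at 50 % allelic
burden (1000 ITD + 1000 wild-type pairs, 2×275 bp), align, and call.  With
no `--reference` given, a built-in synthetic 201 bp amplicon window is used
(the default region label mirrors a real *FLT3* amplicon; any non-repetitive
window of the same size behaves equivalently).

```sh
tandemseek sim --start 150 --length 60 --burden 0.5 --pairs 2000 --outdir sim_out
# sim: 1 combination(s), 2000 read pairs, 2281560 bytes -> sim_out

python -c "from tandemseek import synthetic_window, write_alignment_reference as w; \
           w(synthetic_window(), 'ref.fa')"
bwa index ref.fa
bwa mem ref.fa sim_out/reads_R1.fastq sim_out/reads_R2.fastq > aln.sam

tandemseek seek aln.sam -o itd.vcf
grep -v '^##' itd.vcf
```

```text
#CHROM      POS     ID  REF  ALT              QUAL  FILTER  INFO                                                              FORMAT  SAMPLE
ampliconA   10150   .   A    AAATACTACC...AG  .     PASS    SVTYPE=DUP;SVLEN=60;SF=1000;SR=1000;DP=4000;METHOD=softclip_realign  AF:DP   0.5:4000
```

The one call recovers the simulated truth exactly: a 60 bp tandem
duplication left-aligned at ROI position 150 (contig position 10150), 1000
supporting reads in each direction out of 4000 overlapping (VAF 0.5 = the
simulated burden), above both reporting thresholds, hence `PASS`.

The detection envelope — which (start, length) combinations are detectable
at all — is mapped by the grid harness:

```sh
tandemseek grid --outdir grid_out          # full 201x201 grid, ~1-2 min
tandemseek grid --subsample 5 --outdir q   # quick thinned version
```

`grid_out/summary.tsv` reports the overall detection rate, the per-start
minimum/maximum detectable length, and the insensitive start positions.  On
this machine the full grid gives an overall detection rate of 0.6900
(27,875 of 40,401 combinations), detectable lengths reaching 201 bp (the
full window) for essentially every start, per-start minimum detectable
lengths ranging from 15 to 86 bp, and exactly three blind start positions
at the far amplicon end (199–201), where at most 3 bp of duplicated
sequence remain inside the amplicon.

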