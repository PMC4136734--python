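# ffpemeth

Bisulfite read mapping and genome-wide methylation quantification for
**degraded DNA** — the kind recovered from archival formalin-fixed,
paraffin-embedded (FFPE) tissue: fragmented templates with a broad read-length
distribution, imperfect bisulfite conversion, and all four bisulfite strand
products present after whole-genome amplification.

It is written for epigenomics analysts who want a transparent, fully testable
re-implementation of the classic dual-conversion mapping strategy, including a
synthetic FFPE bisulfite read simulator so that every stage can be validated
against known truth without any external data.

## What it does

Sodium bisulfite converts unmethylated cytosine to uracil (read as T) while
5-methylcytosine is protected, so a read no longer matches the reference
letter-for-letter. The pipeline therefore works in *three-letter* space:

1. **Mapping.** Each read is copied into a C→T version (tag `a`) and a G→A
   version (tag `b`); both are aligned to the Watson and Crick strands of the
   phase-matched converted reference (4 combinations per read). The aligner is
   an exact affine-gap Smith–Waterman (match 1, mismatch −3, gap `5 + 2k`,
   minimum reported score 30); on large references, exact k-mer seeding selects
   candidate windows and the exact DP runs inside each window.
2. **Repeat filtering.** Aligned positions falling in recognized repeat classes
   (Alu, simple repeats, ERVL-MaLR, low-complexity, L1HS/L1M/L1P, LTR ERV,
   segmental duplications, CNVs — one merged BED4 track) are marked; a
   placement is removed if it spans two different repeat types or keeps fewer
   than 20 unmarked aligned bp.
3. **Overlap resolution.** Among multiple placements of one read version, the
   one with the shortest repeat overlap is kept; the surviving `a`/`b`
   placements of the same read are reconciled by containment and
   residual-overlap (≤ 20 bp) rules.
4. **Repeated mapping.** Reads left without a surviving placement and longer
   than 35 bp are split at the midpoint and the fragments re-enter steps 1–3
   (recovering, e.g., chimeric FFPE fragments).
5. **Methylation calling.** At each aligned genomic cytosine the read's
   *original* base is read out (C/G retained ⇒ methylated, T/A ⇒ converted,
   i.e. unmethylated), resolved per strand and context (CpG / CpA). Reported
   statistics: bisulfite conversion rate (converted fraction of cytosine
   observations outside CpG context), pooled CpG/CpA methylation per strand,
   symmetric/asymmetric CpG dyad rates, single-methylation-polymorphism (SMP)
   rates, coverage, depth, and converted-space consistency.

The **simulator** generates a random genome (optionally with planted, genuinely
repetitive repeat families), draws a per-site methylome from per-context
per-strand probabilities, and emits reads with truncated-normal lengths
(default mean 312.6, sd 136.8, range 40–745 bp), i.i.d. conversion failures,
uniform sequencing errors, a mixture of the four bisulfite strand states, and
an optional chimeric-read fraction — with full truth records for parameter
recovery.

## Worked example

`examples/01_simulate_and_run.py` simulates 400 reads over a 20 kb genome and
runs the whole pipeline:

```
reads: 400  fates: {'unique': 387, 'filtered': 13}

methylation summary (generating probabilities in brackets):
  Conversion rate                                  90.1%  [96.7 on unmethylated C]
  Unconverted rate (literal quotient)               9.9%
  Methylation rate of CpG on Watson                64.9%  [65.1]
  Methylation rate of CpG on Crick                 40.7%  [42.7]
  Methylation rate of CpA on Watson                19.1%  [16.4]
  Methylation rate of CpA on Crick                 24.5%  [21.7]
  ...
```

Every read ends in exactly one fate (unique / multi / filtered / unmapped).
The observed CpA rates sit a couple of points above their generating
probabilities and the conversion-rate estimate below the conversion
efficiency — both are the expected signatures of conversion failure (an
unconverted unmethylated cytosine is indistinguishable from a methylated one)
plus the methylated CpA sites counted in the conversion denominator, not
estimation errors. `ffpemeth.score_against_truth` quantifies this exactly.

The other examples show the four-phase mapping on a planted read
(`02_alignment_phases.py`) and the filter rules on constructed placements
(`03_filter_rules.py`).

## Command line

A thin CLI mirrors the stages; staged and monolithic runs are byte-identical:

```bash
ffpemeth simulate --out sim --seed 7
ffpemeth run --reads sim/reads.fastq --ref sim/genome.fa \
             --repeats sim/repeats.bed --out results
# or stage by stage: ffpemeth map | filter | call | report
```

Outputs are plain TSV: a mapping report, a per-placement filter audit,
per-read fates, per-site methylation, a length-bin profile, and three summary
tables (read lengths; alignment; methylation) with a JSON run manifest.

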