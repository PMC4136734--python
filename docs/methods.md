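# Methods

This note documents the models and numerical choices behind `ffpemeth`: the
dual-conversion mapping procedure, the filter rules, the methylation
statistics, the synthetic-data generator, and what the test suite does and
does not demonstrate about real data.

## Dual-conversion ("three-letter") mapping

Bisulfite treatment converts unmethylated C to U (sequenced as T); after
whole-genome amplification the library contains four strand products: the
converted top strand (OT), the converted bottom strand (OB), and their
complements (CTOT, CTOB). A read therefore carries either a C/T-degenerate
or a G/A-degenerate signal, and its orientation is unknown.

Mapping removes the methylation-dependent degeneracy by alignment in
converted space. Each read is duplicated: version `a` with every C
replaced by T, version `b` with every G replaced by A. The reference is
converted the same way on both strands, giving four target sequences per
contig (Watson/Crick × C→T/G→A). Version `a` is aligned to the two C→T
targets and version `b` to the two G→A targets; the four (version ×
strand) combinations correspond one-to-one to the four strand products.
All coordinates are reported on the Watson axis (0-based half-open
internally, 1-based inclusive in report files).

### Aligner

The core aligner is an exact Smith–Waterman local alignment with affine
gaps. Scoring: +1 match, −3 mismatch, a gap of length *k* costs 5 + 2*k*;
placements are reported at score ≥ 30. These are the default parameters
of the classical long-read mapper whose strategy this pipeline follows;
`N` never matches anything (including `N`). The DP kernel is
numba-compiled; traceback is deterministic (first maximal cell in
row-major order; diagonal preferred over vertical over horizontal moves).

Running a full DP against an entire reference for every read is
quadratic and unnecessary; when query × target exceeds 4·10⁶ cells the
aligner first finds exact 16-mer seed matches (every 4th query offset),
clusters them by diagonal, and runs the *exact* DP inside each padded
candidate window (up to 16 windows, so genuine multi-mapping in repeats
is still observed). For smaller targets the full DP is used directly.
The trade-off is the standard seed-and-extend one: a placement with no
exact 16-mer match to its locus (i.e. an error/indel every <16 bp over
the whole read) can be missed; at the error rates this pipeline targets
such reads are effectively unalignable anyway. An optional adapter can
delegate mapping to an external BWA-SW binary (forwarding the recorded
heuristic parameter `z = 50`); it raises an explicit error when the
binary is absent and is never a silent fallback.

Equal-scoring placements are ordered deterministically: score
descending, then contig name, Watson start, Watson before Crick, tag `a`
before `b`. A placement is **unique** when its score strictly exceeds
every other surviving placement of the same query by more than the
configured margin (default 0); a single survivor is unique by
definition. Fragments of a split read compete within their own fragment,
not against the other fragment's placements — a chimeric read's two
halves are genuinely different queries.

## Filter rules

Repeat annotations are supplied as one merged BED4 track (class label in
column 4); the recognized classes for the removal rules are Alu, simple
repeats, ERVL-MaLR, low-complexity, L1HS, L1M, L1P, LTR ERV, Segmental
Dups and CNVs (exact label match; a policy option admits more). Rules,
applied per placement after marking aligned positions that fall inside
annotated intervals:

1. removal if ≥ 2 distinct recognized classes are spanned;
2. removal if unmarked aligned length < 20 bp (positions in *any*
   annotated interval count toward the repeat overlap; only recognized
   classes mark);
3. among placements of one (read, version): keep the one with the
   smallest total repeat overlap in bp, ties broken by the deterministic
   placement order (so equal-overlap ties go to the higher score);
4. between the surviving `a` and `b` placements of one read: if one's
   aligned reference positions are contained in the other's, the
   contained one is removed; with identical coverage the lower-scoring
   one is removed (tie removes `b`) — the higher score carries the true
   conversion phase, since the wrong-phase alignment of the same read
   mismatches at every converted position; with partial overlap, a
   placement whose non-overlapped aligned residue is ≤ 20 bp is removed
   (if both qualify, again the lower-scoring one). Disjoint `a`/`b`
   placements both survive and are flagged `disjoint-loci` in the audit
   file.
5. reads with no surviving placement and longer than 35 bp are split at
   the midpoint; fragments ≥ 35 bp re-enter steps 1–3, with at most two
   split rounds (guaranteeing termination) and full provenance to the
   parent read.

Reads shorter than 40 bp are dropped before mapping (fate `filtered`,
reason `short-read`). Every input read ends in exactly one of
{unique, multi, filtered, unmapped}; the per-read table also records
whether the read had any candidate placement at all, which is what the
alignment summary counts as "mapped".

## Methylation readout

A call reads the *original* (unconverted) base of a read over a genomic
cytosine. Which strand a read informs follows from its phase and mapped
strand: (`a`, Watson) and (`b`, Crick) inform Watson-strand cytosines
via C/T and G/A respectively; (`a`, Crick) and (`b`, Watson) inform
Crick-strand cytosines. Retained C (or G) ⇒ methylated; converted T (or
A) ⇒ unmethylated; anything else ⇒ uninformative. Context is determined
on the site's own strand (CpG: next base G; CpA: next base A; else
"other"; a site at the contig edge is "other").

Statistics:

* **Conversion rate** — converted fraction of informative cytosine calls
  outside CpG context, the standard bisulfite-efficiency control. The
  complementary unconverted quotient is also reported, labelled, since
  both orientations of this ratio appear in the literature. Note that
  methylated CpA sites sit in the denominator, so in tissue with real
  CpA methylation the estimate is `c` times the unmethylated fraction of
  those sites, not `c` itself.
* **Context/strand methylation rates** — call-level pooling
  (methylated / informative calls summed over all sites of the context
  and strand), not the mean of per-site percentages: at the 2–4×
  depths this pipeline targets, per-site percentages are unstable.
* **SMP rate** — over sites with ≥ 2 informative same-strand calls (the
  minimum at which polymorphism is observable), the fraction showing
  both methylated and unmethylated calls; reported per strand and
  pooled.
* **Symmetric / asymmetric CpG rates** — over CpG dyads with ≥ 1
  informative call on each strand; a strand is "methylated" at the dyad
  on a strict majority of its calls (ties count as unmethylated —
  conservative and deterministic).
* **Coverage** — covered fraction (distinct positions under ≥ 1 unique
  placement / genome length), mean depth (aligned bases of unique
  placements / covered positions), and **consistency** (fraction of
  aligned bases matching the phase-converted reference — a definition
  chosen here, as converted-space identity is the quantity the aligner
  actually optimizes).

Degenerate inputs render as `NA` (no informative calls, no eligible
site/dyad, empty read set); percentages print to one decimal place;
Table-1-style means/SDs to two. The standard deviation is the population
form by default (configurable to the sample form — the convention behind
published values of this kind is rarely stated).

## Synthetic data generator

The generator emulates the observable properties of archival-FFPE
bisulfite libraries; defaults are the conditions of a recently archived
sample and are used as-is by the recovery tests:

| parameter | default | meaning |
|---|---|---|
| genome_length | 100 000 bp | random reference, GC 0.42 |
| cpg_enrichment | 1.0 | >1 plants extra CG dinucleotides, <1 depletes |
| repeat_fraction | 0.05 | genome fraction covered by planted 300 bp repeat copies (each class one master motif, so copies truly multi-map) |
| meth CpG W/C | 0.651 / 0.427 | per-site Bernoulli probabilities |
| meth CpA W/C | 0.164 / 0.217 | (aged-block condition: 0.322/0.455 CpG, 0.584/0.658 CpA) |
| conversion | 0.967 | P(unmethylated C reads as T); 0.886 for the aged condition |
| length | truncnorm(312.6, 136.8) on [40, 745] | read lengths (aged: 373.95/146.02 on [40, 657]) |
| error_rate | 0.005 | uniform substitutions |
| strand_mixture | ¼ each | OT/OB/CTOT/CTOB |
| chimera_fraction | 0.02 | reads joining two independent half-length loci |

Conversion failure is i.i.d. per cytosine per read — the simplest model
consistent with a single global conversion rate. Formalin damage is
represented only through the length distribution and the error rate, not
through explicit damage chemistry; errors are substitutions only (no
pyrosequencer homopolymer indel model — indels would conflate aligner
stress-testing with methylation testing). Everything is deterministic
under the config seed (independent substreams for genome, methylome and
reads), and identical configs produce byte-identical FASTQ/truth files.

### Recovery scoring

`score_against_truth` compares pipeline output with the generator's
truth. Mapping accuracy is the fraction of unique placements inside a
true source segment ± 5 bp. Rate recovery is judged against the **expected
observed value**, not the raw generating probability: an unmethylated
site reads methylated with probability (1−c) plus an error term, so at
c = 0.886 raw-probability comparisons would fail by construction. The
expectation is computed exactly per aligned position from the position's
generative origin (which template strand and genomic position produced
it), which keeps the model correct even for the wrong-phase placements
that survive for chimeric reads at disjoint loci and for alignment
extensions across chimera junctions. Each statistic gets a binomial
standard error; the acceptance suite requires |observed − expected| ≤ 3 SE
for every rate across a grid of conversion efficiencies (0.886, 0.967)
and CpG/CpA probabilities (0.32/0.45/0.65, 0.16/0.58), plus ≥ 95%
mapping accuracy in the repeat-free setting.

## Problem sizes and test design

The test and acceptance runs use 100 kb genomes with 5 000 reads (and
smaller fixtures for unit tests) — large enough that every rate estimate
has a sub-percent standard error and seed-and-extend behaves as it would
at scale, while a full run stays in the tens of seconds. The aligner is
additionally pinned, score-for-score, to two independent oracles (a
recursive affine-gap DP and Biopython's `PairwiseAligner`) on random
pairs, and the staged CLI is required to be byte-identical to the
monolithic run and to itself across reruns.

What passing tests show: the mapping/filter/readout machinery is
self-consistent, exactly reproduces the intended rules, and recovers
known parameters from data generated under this package's own model.
What they do not show: behavior under real FFPE artifacts absent from
the model — sequence-context-dependent conversion failure, strand-biased
damage (e.g. C→T deamination independent of bisulfite), indel-rich
pyrosequencing homopolymer errors, amplification bias, or a genuinely
repetitive mammalian genome at full scale.

## Known limitations

* The wrong-phase placement of a read can survive when it lands at a
  locus disjoint from its true-phase placement (mostly chimeric reads);
  such placements are flagged in the audit file but their calls do enter
  the summary statistics, mirroring the filter rules as specified.
* Uniqueness, consistency and depth are defined operationally (see
  above); other reasonable definitions exist and would change the
  corresponding summary rows.
* The seeded aligner path can miss placements with no exact 16-mer
  anchor; desk-scale tests cross-check it against the full DP.
* The repeat filter trusts its annotation track; it does not rediscover
  repeats from sequence.
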