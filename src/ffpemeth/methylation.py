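"""Per-site methylation calls and summary statistics.

A methylation call reads the ORIGINAL (unconverted) base of a read over a
genomic cytosine.  Which genomic strand a read informs follows from its
conversion phase and mapped strand:

====== ======== ======================= ==================
phase  mapped   informative positions   site strand
====== ======== ======================= ==================
'a'    Watson   Watson 'C' (read C/T)   Watson
'a'    Crick    Watson 'G' (read C/T)   Crick
'b'    Watson   Watson 'G' (read G/A)   Crick
'b'    Crick    Watson 'C' (read G/A)   Watson
====== ======== ======================= ==================

(after whole-genome amplification all four bisulfite strand products are
present, so all four combinations occur).  A retained C (or G) means the
cytosine was protected, i.e. methylated; a converted T (or A) means
unmethylated; any other read base is uninformative.

Context is determined on the site's own strand: CpG if the next base on
that strand is G, CpA if it is A, otherwise "other".  The bisulfite
conversion rate is estimated from cytosine observations outside a CpG
context: the fraction that were converted.  (The complementary
unconverted quotient is also exposed, labelled, in the reports.)
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import MappingResult
from .bisulfite import CRICK, WATSON, ConvertedReference, TAG_TO_PHASE
from .seq_io import ReferenceGenome, fmt_pct, fmt_na

CPG = "CpG"
CPA = "CpA"
OTHER = "other"

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class CytosineSite:
    """One genomic cytosine: Watson-axis position, strand, context."""

    contig: str
    pos: int  # 0-based Watson coordinate
    strand: str  # Watson | Crick
    context: str  # CpG | CpA | other


@dataclass(frozen=True)
class MethylationCall:
    """One read-level observation at one cytosine site."""

    site: CytosineSite
    read_id: str
    state: str  # methylated | unmethylated | uninformative


def site_context(genome: ReferenceGenome, contig: str, pos: int,
                 strand: str) -> str:
    """Context of the cytosine at (contig, pos, strand), on its own strand."""
    seq = genome[contig]
    if strand == WATSON:
        nxt = seq[pos + 1] if pos + 1 < len(seq) else "N"
        # Watson site: next base read directly
        return {"G": CPG, "A": CPA}.get(nxt, OTHER)
    # Crick site at Watson 'G': next base on Crick is the complement of the
    # preceding Watson base
    prv = seq[pos - 1] if pos >= 1 else "N"
    return {"C": CPG, "T": CPA}.get(prv, OTHER)


def call_methylation(
    placements: Iterable[MappingResult], genome: ReferenceGenome
) -> list[MethylationCall]:
    """Emit one call per aligned position over a genomic C (or Crick C = Watson G).

    Raises ValueError for a placement that references positions outside its
    contig.
    """
    calls: list[MethylationCall] = []
    for m in placements:
        seq = genome[m.contig]
        if m.ref_end > len(seq) or m.ref_start < 0:
            raise ValueError(
                f"placement {m.query_id}/{m.tag} at {m.contig}:"
                f"{m.ref_start}-{m.ref_end} outside contig (len {len(seq)})"
            )
        phase = TAG_TO_PHASE[m.tag]
        for qpos, wpos in m.aligned_pairs():
            ref_base = seq[wpos]
            read_base = m.read_bases[qpos]
            if phase == "ct":
                # phase 'a': informative at C on the aligned strand
                if m.strand == WATSON and ref_base == "C":
                    site_strand = WATSON
                elif m.strand == CRICK and ref_base == "G":
                    site_strand = CRICK
                else:
                    continue
                if read_base == "C":
                    state = METHYLATED
                elif read_base == "T":
                    state = UNMETHYLATED
                else:
                    state = UNINFORMATIVE
            else:
                # phase 'b': informative at G on the aligned strand; the
                # site lives on the opposite strand
                if m.strand == WATSON and ref_base == "G":
                    site_strand = CRICK
                elif m.strand == CRICK and ref_base == "C":
                    site_strand = WATSON
                else:
                    continue
                if read_base == "G":
                    state = METHYLATED
                elif read_base == "A":
                    state = UNMETHYLATED
                else:
                    state = UNINFORMATIVE
            site = CytosineSite(
                m.contig, wpos, site_strand,
                site_context(genome, m.contig, wpos, site_strand),
            )
            calls.append(MethylationCall(site, m.read_id, state))
    return calls


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionRate:
    """Bisulfite efficiency control over non-CpG-context cytosine calls."""

    n_converted: int
    n_unconverted: int

    @property
    def percent_converted(self) -> float:
        n = self.n_converted + self.n_unconverted
        return 100.0 * self.n_converted / n if n else math.nan

    @property
    def percent_unconverted(self) -> float:
        """The literal unconverted quotient (complement of the rate)."""
        n = self.n_converted + self.n_unconverted
        return 100.0 * self.n_unconverted / n if n else math.nan


def conversion_rate(calls: Sequence[MethylationCall]) -> ConversionRate:
    """Converted fraction of informative cytosine calls outside CpG context."""
    conv = unconv = 0
    for c in calls:
        if c.site.context == CPG:
            continue
        if c.state == UNMETHYLATED:
            conv += 1
        elif c.state == METHYLATED:
            unconv += 1
    return ConversionRate(conv, unconv)


def context_methylation_rate(
    calls: Sequence[MethylationCall], context: str, strand: str
) -> float:
    """Pooled methylation percentage for one context on one strand.

    Call-level pooling: 100 x methylated / informative calls over all
    sites of that context and strand.  NaN when no informative call exists.
    """
    meth = info = 0
    for c in calls:
        if c.site.context != context or c.site.strand != strand:
            continue
        if c.state == METHYLATED:
            meth += 1
            info += 1
        elif c.state == UNMETHYLATED:
            info += 1
    return 100.0 * meth / info if info else math.nan


def _site_counts(
    calls: Sequence[MethylationCall], context: str
) -> dict[CytosineSite, tuple[int, int]]:
    counts: dict[CytosineSite, list[int]] = defaultdict(lambda: [0, 0])
    for c in calls:
        if c.site.context != context:
            continue
        if c.state == METHYLATED:
            counts[c.site][0] += 1
        elif c.state == UNMETHYLATED:
            counts[c.site][1] += 1
    return {s: (m, u) for s, (m, u) in counts.items()}


def smp_rate(
    calls: Sequence[MethylationCall], context: str
) -> dict[str, float]:
    """Single-methylation-polymorphism rate per strand (and combined).

    Over sites with >= 2 informative calls on one strand: the percentage of
    such sites showing both methylated and unmethylated calls.  NaN when no
    site reaches the coverage threshold.
    """
    eligible = {WATSON: 0, CRICK: 0}
    mixed = {WATSON: 0, CRICK: 0}
    for site, (m, u) in _site_counts(calls, context).items():
        if m + u >= 2:
            eligible[site.strand] += 1
            if m > 0 and u > 0:
                mixed[site.strand] += 1
    out: dict[str, float] = {}
    for strand in (WATSON, CRICK):
        out[strand] = (
            100.0 * mixed[strand] / eligible[strand]
            if eligible[strand]
            else math.nan
        )
    tot = eligible[WATSON] + eligible[CRICK]
    out["combined"] = (
        100.0 * (mixed[WATSON] + mixed[CRICK]) / tot if tot else math.nan
    )
    return out


def symmetric_asymmetric_rates(
    calls: Sequence[MethylationCall],
) -> tuple[float, float]:
    """Symmetric / asymmetric CpG methylation over dyads covered on both strands.

    A CpG dyad (Watson C at p, Crick C at p+1) is eligible when each strand
    has >= 1 informative call.  A strand is "methylated" at the dyad when a
    strict majority of its calls are methylated (ties count as
    unmethylated).  Returns percentages of eligible dyads methylated on
    both strands / on exactly one strand; (NaN, NaN) without eligible
    dyads.
    """
    dyads: dict[tuple[str, int], dict[str, tuple[int, int]]] = defaultdict(dict)
    for site, counts in _site_counts(calls, CPG).items():
        if sum(counts) == 0:
            continue
        key = (site.contig, site.pos if site.strand == WATSON else site.pos - 1)
        dyads[key][site.strand] = counts
    eligible = both = one = 0
    for strands in dyads.values():
        if WATSON not in strands or CRICK not in strands:
            continue
        eligible += 1
        states = [
            strands[s][0] > strands[s][1] for s in (WATSON, CRICK)
        ]
        if all(states):
            both += 1
        elif any(states):
            one += 1
    if not eligible:
        return math.nan, math.nan
    return 100.0 * both / eligible, 100.0 * one / eligible


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageStats:
    covered_positions: int
    covered_fraction: float
    mean_depth: float
    consistency_pct: float


def coverage_stats(
    placements: Iterable[MappingResult],
    genome: ReferenceGenome,
    converted: ConvertedReference,
) -> CoverageStats:
    """Coverage of unique placements and converted-space consistency.

    covered fraction = distinct reference positions under >= 1 unique
    placement / genome length; mean depth = total aligned bases of unique
    placements / distinct covered positions; consistency = percentage of
    aligned bases whose phase-converted read base matches the
    phase-converted reference.
    """
    cover: dict[str, np.ndarray] = {
        name: np.zeros(length, dtype=np.int32)
        for name, length in genome.lengths.items()
    }
    matches = aligned = 0
    from .bisulfite import convert_ct, convert_ga

    for m in placements:
        if not m.unique:
            continue
        phase = TAG_TO_PHASE[m.tag]
        conv_read = (
            convert_ct(m.read_bases) if phase == "ct" else convert_ga(m.read_bases)
        )
        ref_seq = converted.get(m.contig, m.strand, phase)
        L = m.contig_length
        arr = cover[m.contig]
        for qpos, wpos in m.aligned_pairs():
            arr[wpos] += 1
            tpos = wpos if m.strand == WATSON else L - 1 - wpos
            aligned += 1
            if conv_read[qpos] == ref_seq[tpos]:
                matches += 1
    covered = int(sum(int((arr > 0).sum()) for arr in cover.values()))
    total_len = genome.total_length
    frac = covered / total_len if total_len else math.nan
    depth = aligned / covered if covered else math.nan
    consistency = 100.0 * matches / aligned if aligned else math.nan
    return CoverageStats(covered, frac, depth, consistency)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class MethylationSummary:
    """The methylation-summary table plus the coverage rows."""

    conversion: ConversionRate
    cpg_watson: float
    cpg_crick: float
    cpa_watson: float
    cpa_crick: float
    symmetric_cpg: float
    asymmetric_cpg: float
    smp_cpg: float
    smp_cpa: float
    coverage: CoverageStats

    def as_table_column(self) -> dict[str, str]:
        return {
            "Conversion rate": fmt_pct(self.conversion.percent_converted),
            "Unconverted rate (literal quotient)": fmt_pct(
                self.conversion.percent_unconverted
            ),
            "Methylation rate of CpG on Watson": fmt_pct(self.cpg_watson),
            "Methylation rate of CpG on Crick": fmt_pct(self.cpg_crick),
            "Methylation rate of CpA on Watson": fmt_pct(self.cpa_watson),
            "Methylation rate of CpA on Crick": fmt_pct(self.cpa_crick),
            "Symmetric CpG methylation rate": fmt_pct(self.symmetric_cpg),
            "Asymmetric CpG methylation rate": fmt_pct(self.asymmetric_cpg),
            "SMP rate of CpG": fmt_pct(self.smp_cpg),
            "SMP rate of CpA": fmt_pct(self.smp_cpa),
        }


def build_methylation_summary(
    calls: Sequence[MethylationCall],
    placements: Sequence[MappingResult],
    genome: ReferenceGenome,
    converted: ConvertedReference,
) -> MethylationSummary:
    sym, asym = symmetric_asymmetric_rates(calls)
    return MethylationSummary(
        conversion=conversion_rate(calls),
        cpg_watson=context_methylation_rate(calls, CPG, WATSON),
        cpg_crick=context_methylation_rate(calls, CPG, CRICK),
        cpa_watson=context_methylation_rate(calls, CPA, WATSON),
        cpa_crick=context_methylation_rate(calls, CPA, CRICK),
        symmetric_cpg=sym,
        asymmetric_cpg=asym,
        smp_cpg=smp_rate(calls, CPG)["combined"],
        smp_cpa=smp_rate(calls, CPA)["combined"],
        coverage=coverage_stats(placements, genome, converted),
    )


def per_site_table(calls: Sequence[MethylationCall]):
    """Per-site rows: contig, 1-based pos, strand, context, counts, percent."""
    import pandas as pd

    rows = []
    counts: dict[CytosineSite, list[int]] = defaultdict(lambda: [0, 0])
    for c in calls:
        if c.state == METHYLATED:
            counts[c.site][0] += 1
        elif c.state == UNMETHYLATED:
            counts[c.site][1] += 1
    for site in sorted(counts, key=lambda s: (s.contig, s.pos, s.strand)):
        m, u = counts[site]
        pct = 100.0 * m / (m + u) if (m + u) else math.nan
        rows.append(
            {
                "contig": site.contig,
                "position": site.pos + 1,
                "strand": site.strand,
                "context": site.context,
                "methylated": m,
                "unmethylated": u,
                "percent_methylation": fmt_na(pct, ".2f"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "position", "strand", "context",
            "methylated", "unmethylated", "percent_methylation",
        ],
    )
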