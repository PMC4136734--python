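"""Synthetic genomes, methylomes and FFPE-degraded bisulfite reads.

The generator produces data with known truth so every pipeline stage has a
parameter-recovery test without external downloads.  Its defaults model
the study conditions this pipeline targets: archival-FFPE DNA read on a
pyrosequencer -- a broad truncated-normal read-length distribution with a
40 bp floor, a single global bisulfite conversion efficiency, uniform
substitution errors, an even mixture of the four bisulfite strand
products left by whole-genome amplification, and a small chimeric-read
fraction from fragmented templates.

Conversion failure is i.i.d. per cytosine per read; formalin damage is
modelled only through the read-length distribution and the error rate,
not through explicit damage chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .bisulfite import CRICK, WATSON, revcomp
from .methylation import (
    CPA,
    CPG,
    MethylationCall,
    conversion_rate,
    context_methylation_rate,
    site_context,
)
from .seq_io import RawRead, ReferenceGenome, RepeatInterval

#: the four bisulfite strand products after whole-genome amplification
STRAND_STATES = ("OT", "OB", "CTOT", "CTOB")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults model a recent-block FFPE sample.

    Methylation probabilities and conversion efficiency default to the
    published whole-sample rates for a fresh archival block; the length
    distribution matches its read-length summary (mean 312.60, sd 136.83,
    range 40-745 bp).
    """

    genome_length: int = 100_000
    contig_name: str = "sim1"
    gc_fraction: float = 0.42
    cpg_enrichment: float = 1.0
    meth_cpg_watson: float = 0.651
    meth_cpg_crick: float = 0.427
    meth_cpa_watson: float = 0.164
    meth_cpa_crick: float = 0.217
    meth_other: float = 0.0
    conversion: float = 0.967
    n_reads: int = 5_000
    length_mean: float = 312.60
    length_sd: float = 136.83
    length_min: int = 40
    length_max: int = 745
    error_rate: float = 0.005
    strand_mixture: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    chimera_fraction: float = 0.02
    repeat_fraction: float = 0.05
    repeat_classes: tuple[str, ...] = ("Alu", "L1M", "simple repeats")
    repeat_unit_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.meth_cpg_watson, self.meth_cpg_crick,
            self.meth_cpa_watson, self.meth_cpa_crick,
            self.meth_other, self.conversion, self.error_rate,
            self.gc_fraction, self.repeat_fraction, self.chimera_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.length_min < 40:
            raise ValueError("minimum read length must be >= 40 bp")
        if abs(sum(self.strand_mixture) - 1.0) > 1e-9:
            raise ValueError("strand mixture must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Where a simulated read came from; chimeras carry two segments."""

    read_id: str
    segments: tuple[tuple[str, int, int, str], ...]  # (contig, start, end, state)

    @property
    def chimeric(self) -> bool:
        return len(self.segments) > 1


Methylome = dict[tuple[str, str, int], bool]  # (contig, strand, watson pos) -> methylated


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, list[RepeatInterval]]:
    """Random reference with optional CpG-density adjustment and planted repeats.

    Repeat regions are genuine sequence copies: every interval of one class
    carries the same master motif, so reads from them truly multi-map.
    Deterministic under the config seed.
    """
    if config.genome_length < 1_000:
        raise ValueError("genome length < 1 kb is too small for meaningful tests")
    rng = _rng(config, 0)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=config.genome_length, p=probs)

    f = config.cpg_enrichment
    if f != 1.0:
        base_cpg = (gc / 2) ** 2
        if f > 1.0:
            p_extra = min((f - 1.0) * base_cpg, 1.0)
            i = 0
            while i < config.genome_length - 1:
                if rng.random() < p_extra:
                    seq[i], seq[i + 1] = "C", "G"
                    i += 2
                else:
                    i += 1
        else:
            for i in range(config.genome_length - 1):
                if seq[i] == "C" and seq[i + 1] == "G" and rng.random() < 1.0 - f:
                    seq[i], seq[i + 1] = "T", "G"

    intervals: list[RepeatInterval] = []
    if config.repeat_fraction > 0:
        unit = config.repeat_unit_length
        n_units = int(round(config.repeat_fraction * config.genome_length / unit))
        motifs = {
            cls: rng.choice(_BASES, size=unit, p=probs)
            for cls in config.repeat_classes
        }
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_units and attempts < 50 * max(n_units, 1):
            attempts += 1
            start = int(rng.integers(0, config.genome_length - unit))
            if any(start < e and start + unit > s for s, e in placed):
                continue
            placed.append((start, start + unit))
        placed.sort()
        for k, (start, end) in enumerate(placed):
            cls = config.repeat_classes[k % len(config.repeat_classes)]
            seq[start:end] = motifs[cls]
            intervals.append(RepeatInterval(config.contig_name, start, end, cls))
        intervals.sort(key=lambda iv: (iv.contig, iv.start))

    genome = ReferenceGenome({config.contig_name: "".join(seq)})
    return genome, intervals


def _site_probability(config: SimulationConfig, strand: str, context: str) -> float:
    if context == CPG:
        return config.meth_cpg_watson if strand == WATSON else config.meth_cpg_crick
    if context == CPA:
        return config.meth_cpa_watson if strand == WATSON else config.meth_cpa_crick
    return config.meth_other


def assign_methylome(
    genome: ReferenceGenome, config: SimulationConfig
) -> Methylome:
    """Draw a true methylation state for every cytosine on both strands.

    Watson sites sit at genomic C positions, Crick sites at genomic G
    positions; each is Bernoulli with its context-and-strand probability.
    Deterministic under the config seed.
    """
    rng = _rng(config, 1)
    methylome: Methylome = {}
    for contig, seq in genome.sequences.items():
        for pos, base in enumerate(seq):
            if base == "C":
                strand = WATSON
            elif base == "G":
                strand = CRICK
            else:
                continue
            p = _site_probability(config, strand, site_context(genome, contig, pos, strand))
            methylome[(contig, strand, pos)] = bool(rng.random() < p)
    return methylome


def _convert_template(
    genome: ReferenceGenome,
    methylome: Methylome,
    contig: str,
    start: int,
    end: int,
    template_strand: str,
    conversion: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one template segment, read in template orientation."""
    watson = genome[contig][start:end]
    if template_strand == WATSON:
        out = []
        for i, base in enumerate(watson):
            if base == "C" and not methylome.get((contig, WATSON, start + i), False):
                out.append("T" if rng.random() < conversion else "C")
            else:
                out.append(base)
        return "".join(out)
    crick = revcomp(watson)
    out = []
    for j, base in enumerate(crick):
        wpos = end - 1 - j
        if base == "C" and not methylome.get((contig, CRICK, wpos), False):
            out.append("T" if rng.random() < conversion else "C")
        else:
            out.append(base)
    return "".join(out)


def _segment_read(
    genome: ReferenceGenome,
    methylome: Methylome,
    contig: str,
    start: int,
    end: int,
    state: str,
    conversion: float,
    rng: np.random.Generator,
) -> str:
    template_strand = WATSON if state in ("OT", "CTOT") else CRICK
    seq = _convert_template(
        genome, methylome, contig, start, end, template_strand, conversion, rng
    )
    if state in ("CTOT", "CTOB"):
        seq = revcomp(seq)
    return seq


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < error_rate:
            choices = [b for b in "ACGT" if b != base]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def generate_reads(
    genome: ReferenceGenome,
    methylome: Methylome,
    config: SimulationConfig,
) -> tuple[list[RawRead], list[TruthRecord]]:
    """Simulate bisulfite reads with known origins and methylation truth.

    Each read samples a locus, a length from the truncated normal, and one
    of the four strand states; unmethylated cytosines on the template
    convert with the configured efficiency (methylated ones never do);
    uniform substitution errors are applied last.  A chimeric read joins
    two independently sampled half-length segments.
    """
    if config.n_reads <= 0:
        raise ValueError("read count must be positive")
    rng = _rng(config, 2)
    a = (config.length_min - config.length_mean) / config.length_sd
    b = (config.length_max - config.length_mean) / config.length_sd
    lengths = stats.truncnorm.rvs(
        a, b, loc=config.length_mean, scale=config.length_sd,
        size=config.n_reads, random_state=rng,
    )
    lengths = np.clip(np.rint(lengths), config.length_min, config.length_max).astype(int)
    contigs = list(genome.sequences)
    contig_lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    contig_p = contig_lens / contig_lens.sum()
    mixture = np.asarray(config.strand_mixture)

    reads: list[RawRead] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        read_id = f"read{i:05d}"
        length = int(lengths[i])
        chimeric = rng.random() < config.chimera_fraction
        seg_lengths = (
            [length // 2, length - length // 2] if chimeric and length >= 2 * config.length_min
            else [length]
        )
        parts: list[str] = []
        segments: list[tuple[str, int, int, str]] = []
        for seg_len in seg_lengths:
            contig = contigs[int(rng.choice(len(contigs), p=contig_p))]
            L = len(genome[contig])
            seg_len = min(seg_len, L)
            start = int(rng.integers(0, L - seg_len + 1))
            state = STRAND_STATES[int(rng.choice(4, p=mixture))]
            parts.append(
                _segment_read(
                    genome, methylome, contig, start, start + seg_len, state,
                    config.conversion, rng,
                )
            )
            segments.append((contig, start, start + seg_len, state))
        bases = _apply_errors("".join(parts), config.error_rate, rng)
        reads.append(RawRead(read_id, bases, (40,) * len(bases)))
        truths.append(TruthRecord(read_id, tuple(segments)))
    return reads, truths


def truncnorm_mean(config: SimulationConfig) -> float:
    """Mean of the configured truncated length distribution (closed form)."""
    a = (config.length_min - config.length_mean) / config.length_sd
    b = (config.length_max - config.length_mean) / config.length_sd
    return float(
        stats.truncnorm.mean(a, b, loc=config.length_mean, scale=config.length_sd)
    )


# ---------------------------------------------------------------------------
# Truth files
# ---------------------------------------------------------------------------


def write_truth_reads(truths: Iterable[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsegment\tcontig\tstart\tend\tstrand_state\n")
        for t in truths:
            for k, (contig, start, end, state) in enumerate(t.segments):
                fh.write(f"{t.read_id}\t{k}\t{contig}\t{start}\t{end}\t{state}\n")


def write_truth_methylome(methylome: Methylome, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstrand\tposition\tmethylated\n")
        for (contig, strand, pos) in sorted(methylome):
            fh.write(f"{contig}\t{strand}\t{pos}\t{int(methylome[(contig, strand, pos)])}\n")


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _call_probabilities(methylated: bool, conversion: float, error_rate: float):
    """P(methylated-looking) and P(unmethylated-looking) for one observation."""
    e = error_rate
    if methylated:
        pm, pu = (1 - e), e / 3
    else:
        c = conversion
        pm = (1 - c) * (1 - e) + c * e / 3
        pu = c * (1 - e) + (1 - c) * e / 3
    return pm, pu


def expected_observed_fraction(
    methylated: bool, conversion: float, error_rate: float
) -> float:
    """Expected methylated fraction among informative calls at one site."""
    pm, pu = _call_probabilities(methylated, conversion, error_rate)
    return pm / (pm + pu)


def _read_base_distribution(
    truth: TruthRecord,
    parent_pos: int,
    genome: ReferenceGenome,
    methylome: Methylome,
    config: SimulationConfig,
) -> dict[str, float]:
    """Exact base distribution at one read position, from its known origin.

    Every simulated read position derives deterministically from one
    template position of one truth segment; its base distribution follows
    from the template base, the site's true methylation state, the
    conversion efficiency and the uniform substitution error -- regardless
    of where the aligner later placed it.
    """
    from .bisulfite import complement

    # locate the covering segment and the local offset within it
    cum = 0
    contig = start = end = state = None
    for contig, start, end, state in truth.segments:
        seg_len = end - start
        if parent_pos < cum + seg_len:
            break
        cum += seg_len
    j = parent_pos - cum
    template = WATSON if state in ("OT", "CTOT") else CRICK
    # OT reads run with the Watson template, OB with Crick; the CT* states
    # are their reverse complements, so their j-th base comes from the far end
    origin = start + j if state in ("OT", "CTOB") else end - 1 - j
    watson_base = genome[contig][origin]
    tb = watson_base if template == WATSON else complement(watson_base)
    # bisulfite on the template strand
    post_bis: dict[str, float]
    if tb == "C":
        m = methylome.get((contig, template, origin), False)
        c = config.conversion
        p_c = 1.0 if m else (1.0 - c)
        post_bis = {"C": p_c, "T": 1.0 - p_c}
    else:
        post_bis = {tb: 1.0}
    # orientation: complement strands present the complement of the template
    if state in ("CTOT", "CTOB"):
        post_bis = {complement(b): p for b, p in post_bis.items()}
    # uniform substitution error
    e = config.error_rate
    dist = {b: 0.0 for b in "ACGT"}
    for b, p in post_bis.items():
        dist[b] += p * (1.0 - e)
        for other in "ACGT":
            if other != b:
                dist[other] += p * e / 3.0
    return dist


def _expected_call_distribution(
    placement,
    truth: TruthRecord,
    genome: ReferenceGenome,
    methylome: Methylome,
    config: SimulationConfig,
):
    """Yield (site_strand, context, w, q) per informative position of a placement.

    ``q`` is the probability that a call at the position reads methylated
    given that it is informative, and ``w`` the probability that it is
    informative at all; both follow exactly from the read position's
    generative origin (:func:`_read_base_distribution`), so the model
    remains correct for wrong-phase survivors of chimeric reads, alignment
    extensions across chimera junctions, and mismapped placements alike.
    """
    from .bisulfite import TAG_TO_PHASE

    seq = genome[placement.contig]
    phase = TAG_TO_PHASE[placement.tag]
    meth_base, unmeth_base = ("C", "T") if phase == "ct" else ("G", "A")
    for qpos, wpos in placement.aligned_pairs():
        ref_base = seq[wpos]
        if phase == "ct":
            if placement.strand == WATSON and ref_base == "C":
                site_strand = WATSON
            elif placement.strand == CRICK and ref_base == "G":
                site_strand = CRICK
            else:
                continue
        else:
            if placement.strand == WATSON and ref_base == "G":
                site_strand = CRICK
            elif placement.strand == CRICK and ref_base == "C":
                site_strand = WATSON
            else:
                continue
        dist = _read_base_distribution(
            truth, placement.frag_offset + qpos, genome, methylome, config
        )
        w = dist[meth_base] + dist[unmeth_base]
        if w <= 0.0:
            continue
        q = dist[meth_base] / w
        yield (
            site_strand,
            site_context(genome, placement.contig, wpos, site_strand),
            w,
            q,
        )


def score_against_truth(
    placements: Sequence,
    truths: Sequence[TruthRecord],
    calls: Sequence[MethylationCall] | None = None,
    methylome: Methylome | None = None,
    config: SimulationConfig | None = None,
    genome: ReferenceGenome | None = None,
    tolerance_bp: int = 5,
) -> dict:
    """Compare pipeline output with the generator's truth.

    Mapping accuracy is the fraction of unique placements lying within
    +/- ``tolerance_bp`` of a true source segment of their read.  When
    calls, methylome, config and genome are supplied, each summary rate
    is compared with its expected observed value under the generative
    model (see :func:`_expected_call_distribution`), with a binomial
    standard error.  A placement whose read id is unknown to the truth
    set raises ValueError.
    """
    truth_by_id: Mapping[str, TruthRecord] = {t.read_id: t for t in truths}
    n_unique = correct = 0
    for m in placements:
        if m.read_id not in truth_by_id:
            raise ValueError(f"placement read id {m.read_id!r} not in truth set")
        if not m.unique:
            continue
        n_unique += 1
        for contig, start, end, _state in truth_by_id[m.read_id].segments:
            if (
                m.contig == contig
                and m.ref_start >= start - tolerance_bp
                and m.ref_end <= end + tolerance_bp
            ):
                correct += 1
                break
    report: dict = {
        "n_unique_placements": n_unique,
        "mapping_accuracy": (correct / n_unique) if n_unique else math.nan,
    }
    if calls is None or methylome is None or config is None or genome is None:
        return report

    expected_wq: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for m in placements:
        for strand, context, w, q in _expected_call_distribution(
            m, truth_by_id[m.read_id], genome, methylome, config
        ):
            expected_wq.setdefault((context, strand), []).append((w, q))

    def _rate_entry(observed_pct, wq, invert=False):
        if not wq:
            return {"observed": math.nan, "expected": math.nan,
                    "se": math.nan, "n": 0, "z": math.nan}
        arr = np.asarray(wq, dtype=float)
        ws, qs = arr[:, 0], arr[:, 1]
        if invert:
            qs = 1.0 - qs
        wsum = ws.sum()
        expected = float((ws * qs).sum() / wsum)
        se = float(np.sqrt((ws * qs * (1 - qs)).sum()) / wsum)
        obs = observed_pct / 100.0
        z = (obs - expected) / se if se > 0 else math.nan
        return {"observed": 100 * obs, "expected": 100 * expected,
                "se": 100 * se, "n": int(round(wsum)), "z": float(z)}

    rates: dict[str, dict[str, float]] = {}
    for context, strand, name in (
        (CPG, WATSON, "cpg_watson"),
        (CPG, CRICK, "cpg_crick"),
        (CPA, WATSON, "cpa_watson"),
        (CPA, CRICK, "cpa_crick"),
    ):
        rates[name] = _rate_entry(
            context_methylation_rate(calls, context, strand),
            expected_wq.get((context, strand), []),
        )
    conv_wq = [
        pair
        for (context, _strand), pairs in expected_wq.items()
        if context != CPG
        for pair in pairs
    ]
    rates["conversion"] = _rate_entry(
        conversion_rate(calls).percent_converted, conv_wq, invert=True
    )
    report["rates"] = rates
    return report
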