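"""In-silico bisulfite conversion phases for reads and reference.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
alignment is therefore done in "three-letter" space, where the
methylation-dependent base difference is removed.  Two phases exist
because, after whole-genome amplification, reads can derive from either
the converted template or its complement:

* phase ``'a'``: every C replaced by T (read derives from a converted strand
  read in its own orientation);
* phase ``'b'``: every G replaced by A (read is the complement of a
  converted strand).

Each read is carried in both phases; the reference is converted in both
phases on both strands (four sequences per contig).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import RawRead, ReferenceGenome, VALID_BASES

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")
_COMP = str.maketrans("ACGTN", "TGCAN")

WATSON = "Watson"
CRICK = "Crick"
STRANDS = (WATSON, CRICK)
PHASES = ("ct", "ga")
TAG_TO_PHASE = {"a": "ct", "b": "ga"}


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise ValueError(f"invalid base {ch!r} at position {i}")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    _validate(seq)
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def convert_ct(seq: str) -> str:
    """Replace every C by T; other bases (including N) unchanged."""
    _validate(seq)
    return seq.translate(_CT)


def convert_ga(seq: str) -> str:
    """Replace every G by A; other bases (including N) unchanged."""
    _validate(seq)
    return seq.translate(_GA)


@dataclass(frozen=True)
class TaggedRead:
    """A read plus its conversion phase tag ('a': C->T, 'b': G->A).

    The original bases are retained for the later methylation readout; the
    converted bases are what the aligner sees.
    """

    read: RawRead
    tag: str
    converted_bases: str

    def __post_init__(self) -> None:
        assert self.tag in ("a", "b")
        assert len(self.converted_bases) == len(self.read.bases)


def make_tagged_versions(read: RawRead) -> tuple[TaggedRead, TaggedRead]:
    """Produce the 'a' (C->T) and 'b' (G->A) versions of a read."""
    if len(read.bases) == 0:
        raise ValueError(f"read {read.id!r}: empty read cannot be tagged")
    return (
        TaggedRead(read, "a", convert_ct(read.bases)),
        TaggedRead(read, "b", convert_ga(read.bases)),
    )


class ConvertedReference:
    """Per contig, the four phase-converted sequences.

    Keys: (contig, strand, phase) with strand in {Watson, Crick} and phase
    in {"ct", "ga"}.  The Crick sequence is the reverse complement of the
    Watson contig, converted after complementing.  Lengths always match
    the unconverted contig.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self._seqs: dict[tuple[str, str, str], str] = {}
        for name, watson in genome.sequences.items():
            crick = revcomp(watson)
            self._seqs[(name, WATSON, "ct")] = convert_ct(watson)
            self._seqs[(name, WATSON, "ga")] = convert_ga(watson)
            self._seqs[(name, CRICK, "ct")] = convert_ct(crick)
            self._seqs[(name, CRICK, "ga")] = convert_ga(crick)

    @property
    def contigs(self) -> list[str]:
        return list(self.genome.sequences)

    def get(self, contig: str, strand: str, phase: str) -> str:
        return self._seqs[(contig, strand, phase)]

    def contig_length(self, contig: str) -> int:
        return len(self.genome.sequences[contig])


def build_converted_reference(genome: ReferenceGenome) -> ConvertedReference:
    """Build the four converted sequence sets (Watson/Crick x C->T/G->A)."""
    return ConvertedReference(genome)
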