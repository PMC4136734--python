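"""Readers and writers for the formats the pipeline touches.

FASTA / FASTQ / qual parsing is delegated to Biopython; a thin validation
layer on top supplies the precise error reporting the pipeline contracts
require (line-addressed format errors, length checks, alphabet checks).

Coordinate convention: all genomic intervals are 0-based half-open in
memory; human-facing report files render 1-based inclusive coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import PairedFastaQualIterator
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (FASTA/FASTQ/qual/BED)."""


@dataclass(frozen=True)
class RawRead:
    """One sequencing read: id, bases over {A,C,G,T,N}, optional Phred scores."""

    id: str
    bases: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("read with empty id")
        if len(self.bases) < 1:
            raise FormatError(f"read {self.id!r}: empty sequence")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise FormatError(
                f"read {self.id!r}: invalid base(s) {sorted(bad)!r} "
                "(expected A/C/G/T/N)"
            )
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferenceGenome:
    """Named Watson-strand sequences; the Crick strand is derived on demand."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if any(not name for name in self.sequences):
            raise FormatError("contig with empty name")
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r}: invalid base(s) {sorted(bad)!r}"
                )
            if not seq:
                raise FormatError(f"contig {name!r}: empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]


@dataclass(frozen=True, order=True)
class RepeatInterval:
    """BED-style repeat annotation: 0-based half-open, class label kept verbatim."""

    contig: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"repeat interval {self.contig}:{self.start}-{self.end}: "
                "start must be < end"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _check_fasta_head(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header "
                    f"starting with '>', got {line.strip()[:30]!r}"
                )
            return
    raise FormatError(f"{path}: empty FASTA file")


def read_fasta(path: str | Path, qual_path: str | Path | None = None) -> list[RawRead]:
    """Read FASTA records as reads, optionally pairing a parallel .qual file.

    Lowercase input is accepted and normalized to uppercase; record order is
    preserved.
    """
    _check_fasta_head(path)
    reads: list[RawRead] = []
    if qual_path is None:
        for rec in SeqIO.parse(str(path), "fasta"):
            reads.append(RawRead(rec.id, str(rec.seq).upper()))
    else:
        with open(path) as fa, open(qual_path) as qu:
            for rec in PairedFastaQualIterator(fa, qu):
                reads.append(
                    RawRead(
                        rec.id,
                        str(rec.seq).upper(),
                        tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
    return reads


def read_reference(path: str | Path) -> ReferenceGenome:
    """Read a FASTA reference into a :class:`ReferenceGenome`."""
    _check_fasta_head(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return ReferenceGenome(seqs)


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read 4-line FASTQ records with Sanger/Phred+33 qualities.

    Both FASTQ '+'-line dialects (bare '+' and repeated id) are accepted.
    A truncated or inconsistent record raises :class:`FormatError` naming
    the record index.
    """
    reads: list[RawRead] = []  # a zero-byte file is a valid empty FASTQ
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                RawRead(
                    rec.id,
                    str(rec.seq).upper(),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as err:
        raise FormatError(f"{path}: record {len(reads) + 1}: {err}") from err
    return reads


def write_fasta(records: Mapping[str, str] | Iterable[RawRead], path: str | Path) -> None:
    """Write a reference (mapping) or reads (iterable of RawRead) as FASTA."""
    if isinstance(records, Mapping):
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in records.items()]
    else:
        recs = [SeqRecord(Seq(r.bases), id=r.id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    recs = []
    for r in reads:
        qual = r.quality if r.quality is not None else (40,) * len(r)
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(qual)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# Repeat BED
# ---------------------------------------------------------------------------


def read_repeat_bed(path: str | Path) -> list[RepeatInterval]:
    """Read BED4 repeat annotations (contig, start, end, class).

    Output is sorted by (contig, start); class labels are kept verbatim.
    """
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            contig, start_s, end_s, cls = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from err
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            intervals.append(RepeatInterval(contig, start, end, cls))
    intervals.sort(key=lambda iv: (iv.contig, iv.start, iv.end, iv.repeat_class))
    return intervals


def write_repeat_bed(intervals: Iterable[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.repeat_class}\n")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

TABLE1_ROWS = [
    "Raw wells",
    "Key pass wells",
    "Passed filter wells",
    "Total bases",
    "Length average",
    "Length std deviation",
    "Longest read length",
    "Shortest read length",
    "Median read length",
]

TABLE2_ROWS = [
    "Total number of reads",
    "Total number of reads mapped",
    "Total number of reads mapped/Total number of reads",
    "Total number of reads uniquely mapped",
    "Total number of reads uniquely mapped/Total number of reads",
    "Total length (bp) of all reads",
    "Total length (bp) of unique mapped reads",
    "Total length of unique mapped reads/Total length of all reads",
    "Total bases of unique mapped reads",
    "Total bases of unique mapped reads/Total bases of all reads",
    "Consistency rate",
    "Total number of bases covered in the genome",
    "Depth (x-fold)",
]

TABLE3_ROWS = [
    "Conversion rate",
    "Unconverted rate (literal quotient)",
    "Methylation rate of CpG on Watson",
    "Methylation rate of CpG on Crick",
    "Methylation rate of CpA on Watson",
    "Methylation rate of CpA on Crick",
    "Symmetric CpG methylation rate",
    "Asymmetric CpG methylation rate",
    "SMP rate of CpG",
    "SMP rate of CpA",
]


def fmt_na(value, spec: str = "") -> str:
    """Render a value, mapping None/NaN to 'NA'."""
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return format(value, spec) if spec else str(value)


def fmt_pct(value) -> str:
    """Percentages rendered to one decimal place ('70.6%'); NA passthrough."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.1f}%"


def _write_table(rows: Sequence[str], columns: Mapping[str, Mapping[str, str]],
                 path: Path) -> None:
    samples = list(columns)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(samples) + "\n")
        for row in rows:
            vals = [columns[s].get(row, "NA") for s in samples]
            fh.write(row + "\t" + "\t".join(vals) + "\n")


def write_report_tables(summaries: Mapping[str, tuple], out_dir: str | Path) -> dict[str, Path]:
    """Write the three summary tables (read lengths, alignment, methylation).

    ``summaries`` maps sample name -> (ReadLengthSummary, AlignmentSummary,
    MethylationSummary); any element may be None, in which case its table
    column is all-NA.  Returns the written paths keyed 'table1'..'table3'.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1_cols: dict[str, dict[str, str]] = {}
    t2_cols: dict[str, dict[str, str]] = {}
    t3_cols: dict[str, dict[str, str]] = {}
    for sample, (rls, als, ms) in summaries.items():
        t1_cols[sample] = rls.as_table_column() if rls is not None else {}
        t2_cols[sample] = als.as_table_column() if als is not None else {}
        t3_cols[sample] = ms.as_table_column() if ms is not None else {}
    paths = {
        "table1": out / "table1_read_lengths.tsv",
        "table2": out / "table2_alignment.tsv",
        "table3": out / "table3_methylation.tsv",
    }
    _write_table(TABLE1_ROWS, t1_cols, paths["table1"])
    _write_table(TABLE2_ROWS, t2_cols, paths["table2"])
    _write_table(TABLE3_ROWS, t3_cols, paths["table3"])
    return paths
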