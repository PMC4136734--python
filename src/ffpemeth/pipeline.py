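"""End-to-end orchestration: conversion -> mapping -> filtering -> calling -> reports.

Every stage is file-mediated: it loads its inputs from the documented
TSV/FASTA/FASTQ/BED interfaces and writes its outputs, so staged execution
(the CLI subcommands) and monolithic execution (:func:`run_pipeline`,
which simply calls the stages in order on the same files) are identical by
construction.  All stages are deterministic; a run manifest captures the
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._version import __version__
from .align import (
    AlignmentParams,
    MappingResult,
    SeedIndex,
    map_tagged_read,
)
from .bisulfite import build_converted_reference, make_tagged_versions
from .filters import (
    REASON_SHORT_READ,
    RepeatIndex,
    RepeatPolicy,
    filter_repeat_hit,
    mark_repeats,
    resolve_multimapping,
    resolve_version_overlap,
    split_read,
)
from .methylation import (
    build_methylation_summary,
    call_methylation,
    per_site_table,
)
from .seq_io import (
    RawRead,
    read_fasta,
    read_fastq,
    read_reference,
    read_repeat_bed,
    write_report_tables,
)
from .summaries import (
    ReadFate,
    bin_profile,
    build_alignment_summary,
    summarize_lengths,
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    reads: str
    reference: str
    out_dir: str
    repeats: str | None = None
    params: AlignmentParams = field(default_factory=AlignmentParams)
    policy: RepeatPolicy = field(default_factory=RepeatPolicy)
    sample_name: str = "sample"
    bin_width: int = 40
    std_ddof: int = 0
    raw_wells: int | None = None
    key_pass_wells: int | None = None

    def validate(self) -> None:
        for label, path in (("reads", self.reads), ("reference", self.reference),
                            ("repeats", self.repeats)):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"validation: {label} path {path!r} does not exist")
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)


def load_reads(path: str | Path) -> list[RawRead]:
    """Load reads from FASTQ (default) or FASTA by extension."""
    p = str(path)
    if p.endswith((".fa", ".fasta", ".fna")):
        return read_fasta(p)
    return read_fastq(p)


# ---------------------------------------------------------------------------
# TSV serialization of placements
# ---------------------------------------------------------------------------

_CAND_COLUMNS = [
    "read_id", "query_id", "frag_offset", "query_length", "tag", "contig",
    "strand", "start", "end", "read_start", "read_end", "score", "cigar",
]
_PLACEMENT_COLUMNS = _CAND_COLUMNS + ["unique"]


def _placement_row(m: MappingResult, unique_col: bool) -> list[str]:
    row = [
        m.read_id, m.query_id, str(m.frag_offset), str(len(m.read_bases)),
        m.tag, m.contig, m.strand,
        str(m.ref_start + 1), str(m.ref_end),  # 1-based inclusive in reports
        str(m.read_start + 1), str(m.read_end),
        str(m.score), m.cigar,
    ]
    if unique_col:
        row.append(str(int(m.unique)))
    return row


def write_placements(
    placements: Sequence[MappingResult], path: str | Path, unique_col: bool
) -> None:
    cols = _PLACEMENT_COLUMNS if unique_col else _CAND_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in placements:
            fh.write("\t".join(_placement_row(m, unique_col)) + "\n")


def load_placements(
    path: str | Path,
    reads_by_id: dict[str, RawRead],
    contig_lengths: dict[str, int],
) -> list[MappingResult]:
    out: list[MappingResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            read_id = f[idx["read_id"]]
            off = int(f[idx["frag_offset"]])
            qlen = int(f[idx["query_length"]])
            parent = reads_by_id[read_id]
            m = MappingResult(
                read_id=read_id,
                query_id=f[idx["query_id"]],
                tag=f[idx["tag"]],
                contig=f[idx["contig"]],
                strand=f[idx["strand"]],
                ref_start=int(f[idx["start"]]) - 1,
                ref_end=int(f[idx["end"]]),
                read_start=int(f[idx["read_start"]]) - 1,
                read_end=int(f[idx["read_end"]]),
                score=int(f[idx["score"]]),
                cigar=f[idx["cigar"]],
                read_bases=parent.bases[off : off + qlen],
                contig_length=contig_lengths[f[idx["contig"]]],
                frag_offset=off,
            )
            if "unique" in idx:
                m.unique = bool(int(f[idx["unique"]]))
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# Stage 1: mapping
# ---------------------------------------------------------------------------


def map_stage(
    reads_path: str | Path,
    reference_path: str | Path,
    out_candidates: str | Path,
    params: AlignmentParams = AlignmentParams(),
    policy: RepeatPolicy = RepeatPolicy(),
) -> list[MappingResult]:
    """Map both tagged versions of every read; write the candidate table.

    Reads shorter than ``policy.min_read_len`` are not mapped (the filter
    stage records their fate).
    """
    reads = load_reads(reads_path)
    genome = read_reference(reference_path)
    converted = build_converted_reference(genome)
    index = SeedIndex(converted)
    candidates: list[MappingResult] = []
    for read in reads:
        if len(read) < policy.min_read_len:
            continue
        va, vb = make_tagged_versions(read)
        candidates.extend(map_tagged_read(va, vb, converted, params, index))
    write_placements(candidates, out_candidates, unique_col=False)
    return candidates


# ---------------------------------------------------------------------------
# Stage 2+3+4: filtering, overlap resolution, repeated mapping
# ---------------------------------------------------------------------------


@dataclass
class AuditRow:
    read_id: str
    query_id: str
    tag: str
    fate: str  # kept | removed | unmapped
    reason: str
    n_repeat_classes: int
    unmarked_m_bp: int


def _steps_2_3(
    by_query: dict[str, list[MappingResult]],
    repeat_index: RepeatIndex,
    policy: RepeatPolicy,
    audit: list[AuditRow],
) -> dict[str, list[MappingResult]]:
    """Apply repeat filtering and overlap resolution per query; audit everything."""
    survivors_by_query: dict[str, list[MappingResult]] = {}
    for query_id, hits in by_query.items():
        per_tag: dict[str, list[MappingResult]] = {"a": [], "b": []}
        for m in hits:
            mark_repeats(m, repeat_index, policy)
            keep, reason = filter_repeat_hit(m, policy)
            if keep:
                per_tag[m.tag].append(m)
            else:
                audit.append(
                    AuditRow(m.read_id, query_id, m.tag, "removed", reason,
                             len(set(m.repeat_marks.values())),
                             m.aligned_length - len(m.repeat_marks))
                )
        resolved: dict[str, MappingResult | None] = {}
        for tag in ("a", "b"):
            kept, removed = resolve_multimapping(per_tag[tag])
            resolved[tag] = kept
            for m in removed:
                audit.append(
                    AuditRow(m.read_id, query_id, tag, "removed",
                             "multimap-longer-repeat-overlap",
                             len(set(m.repeat_marks.values())),
                             m.aligned_length - len(m.repeat_marks))
                )
        survivors, removed_pairs, disjoint = resolve_version_overlap(
            resolved["a"], resolved["b"], policy
        )
        for m, reason in removed_pairs:
            audit.append(
                AuditRow(m.read_id, query_id, m.tag, "removed", reason,
                         len(set(m.repeat_marks.values())),
                         m.aligned_length - len(m.repeat_marks))
            )
        for m in survivors:
            audit.append(
                AuditRow(m.read_id, query_id, m.tag, "kept",
                         "disjoint-loci" if disjoint else "",
                         len(set(m.repeat_marks.values())),
                         m.aligned_length - len(m.repeat_marks))
            )
        if survivors:
            survivors_by_query[query_id] = survivors
    return survivors_by_query


def _mark_unique(survivors_by_query: dict[str, list[MappingResult]],
                 params: AlignmentParams) -> None:
    """Placements compete within one query; a strict top scorer is unique."""
    for hits in survivors_by_query.values():
        if len(hits) == 1:
            hits[0].unique = True
            continue
        ranked = sorted(hits, key=MappingResult.sort_key)
        if ranked[0].score > ranked[1].score + params.unique_margin:
            ranked[0].unique = True


def filter_stage(
    candidates_path: str | Path,
    reads_path: str | Path,
    reference_path: str | Path,
    repeats_path: str | Path | None,
    out_dir: str | Path,
    params: AlignmentParams = AlignmentParams(),
    policy: RepeatPolicy = RepeatPolicy(),
) -> tuple[list[MappingResult], dict[str, ReadFate]]:
    """Steps 2-4: repeat/overlap filters plus repeated mapping of unmapped reads.

    Writes ``placements.tsv`` (surviving placements with unique flags),
    ``audit.tsv`` (per-placement fates) and ``fates.tsv`` (per-read
    conservation accounting) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = load_reads(reads_path)
    reads_by_id = {r.id: r for r in reads}
    genome = read_reference(reference_path)
    converted = build_converted_reference(genome)
    index = SeedIndex(converted)
    repeat_index = RepeatIndex(
        read_repeat_bed(repeats_path) if repeats_path is not None else []
    )
    candidates = load_placements(candidates_path, reads_by_id, genome.lengths)

    by_query: dict[str, list[MappingResult]] = {}
    for m in candidates:
        by_query.setdefault(m.query_id, []).append(m)

    audit: list[AuditRow] = []
    survivors_by_query = _steps_2_3(by_query, repeat_index, policy, audit)

    # step 4: repeated mapping of reads with no surviving placement
    had_candidates: set[str] = {m.read_id for m in candidates}
    surviving_reads = {
        hits[0].read_id for hits in survivors_by_query.values()
    }
    pending: list[tuple[RawRead, int, int]] = []  # (fragment, offset, round)
    for read in reads:
        if read.id in surviving_reads or len(read) < policy.min_read_len:
            continue
        if len(read) > policy.remap_min_len:
            for frag_id, off, frag in split_read(read, policy):
                pending.append((frag, off, 1))
    while pending:
        frag, off, round_no = pending.pop(0)
        va, vb = make_tagged_versions(frag)
        parent_root = frag.id.split("|", 1)[0]
        frag_hits = map_tagged_read(
            va, vb, converted, params, index,
            query_id=frag.id, parent_id=parent_root, frag_offset=off,
        )
        if frag_hits:
            had_candidates.add(parent_root)
            frag_survivors = _steps_2_3(
                {frag.id: frag_hits}, repeat_index, policy, audit
            )
            survivors_by_query.update(frag_survivors)
            if frag_survivors:
                continue
        if round_no < policy.max_split_rounds and len(frag) > policy.remap_min_len:
            for sub_id, sub_off, sub in split_read(frag, policy, base_id=frag.id):
                pending.append((sub, off + sub_off, round_no + 1))

    _mark_unique(survivors_by_query, params)

    placements: list[MappingResult] = []
    for query_id in sorted(survivors_by_query):
        placements.extend(
            sorted(survivors_by_query[query_id], key=MappingResult.sort_key)
        )

    # per-read conservation accounting
    removal_reason: dict[str, str] = {}
    for row in audit:
        if row.fate == "removed" and row.read_id not in removal_reason:
            removal_reason[row.read_id] = row.reason
    unique_reads = {m.read_id for m in placements if m.unique}
    multi_reads = {m.read_id for m in placements} - unique_reads
    fates: dict[str, ReadFate] = {}
    for read in reads:
        rid = read.id
        if len(read) < policy.min_read_len:
            fates[rid] = ReadFate(rid, "filtered", REASON_SHORT_READ, False)
        elif rid in unique_reads:
            fates[rid] = ReadFate(rid, "unique", None, True)
        elif rid in multi_reads:
            fates[rid] = ReadFate(rid, "multi", None, True)
        elif rid in had_candidates:
            fates[rid] = ReadFate(
                rid, "filtered", removal_reason.get(rid, "filtered"), True
            )
        else:
            fates[rid] = ReadFate(rid, "unmapped", None, False)

    write_placements(placements, out / "placements.tsv", unique_col=True)
    with open(out / "audit.tsv", "w") as fh:
        fh.write("read_id\tquery_id\ttag\tfate\treason\tn_repeat_classes\tunmarked_m_bp\n")
        for row in audit:
            fh.write(
                f"{row.read_id}\t{row.query_id}\t{row.tag}\t{row.fate}\t"
                f"{row.reason}\t{row.n_repeat_classes}\t{row.unmarked_m_bp}\n"
            )
    with open(out / "fates.tsv", "w") as fh:
        fh.write("read_id\tfate\treason\tmapped\n")
        for read in reads:
            f = fates[read.id]
            fh.write(
                f"{f.read_id}\t{f.fate}\t{f.reason or ''}\t{int(f.mapped)}\n"
            )
    return placements, fates


def load_fates(path: str | Path) -> dict[str, ReadFate]:
    fates: dict[str, ReadFate] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, fate, reason, mapped = line.rstrip("\n").split("\t")
            fates[rid] = ReadFate(rid, fate, reason or None, bool(int(mapped)))
    return fates


# ---------------------------------------------------------------------------
# Stage 5: methylation calling
# ---------------------------------------------------------------------------


def call_stage(
    placements_path: str | Path,
    reads_path: str | Path,
    reference_path: str | Path,
    out_dir: str | Path,
):
    """Convert surviving placements into calls; write calls and per-site tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = load_reads(reads_path)
    reads_by_id = {r.id: r for r in reads}
    genome = read_reference(reference_path)
    placements = load_placements(placements_path, reads_by_id, genome.lengths)
    calls = call_methylation(placements, genome)
    with open(out / "calls.tsv", "w") as fh:
        fh.write("read_id\tcontig\tposition\tstrand\tcontext\tstate\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.site.contig}\t{c.site.pos + 1}\t"
                f"{c.site.strand}\t{c.site.context}\t{c.state}\n"
            )
    per_site_table(calls).to_csv(out / "per_site.tsv", sep="\t", index=False)
    return calls


def load_calls(path: str | Path):
    from .methylation import CytosineSite, MethylationCall

    calls = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, contig, pos, strand, context, state = line.rstrip("\n").split("\t")
            calls.append(
                MethylationCall(
                    CytosineSite(contig, int(pos) - 1, strand, context), rid, state
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Stage 6: reports
# ---------------------------------------------------------------------------


def report_stage(
    reads_path: str | Path,
    fates_path: str | Path,
    placements_path: str | Path,
    calls_path: str | Path,
    reference_path: str | Path,
    out_dir: str | Path,
    sample_name: str = "sample",
    bin_width: int = 40,
    std_ddof: int = 0,
    raw_wells: int | None = None,
    key_pass_wells: int | None = None,
):
    """Write the three summary tables and the length-bin profile."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = load_reads(reads_path)
    reads_by_id = {r.id: r for r in reads}
    genome = read_reference(reference_path)
    converted = build_converted_reference(genome)
    placements = load_placements(placements_path, reads_by_id, genome.lengths)
    fates = load_fates(fates_path)
    calls = load_calls(calls_path)

    rls = summarize_lengths(reads, ddof=std_ddof,
                            raw_wells=raw_wells, key_pass_wells=key_pass_wells)
    msum = build_methylation_summary(calls, placements, genome, converted)
    asum = build_alignment_summary(reads, fates, placements, msum.coverage)
    write_report_tables({sample_name: (rls, asum, msum)}, out)
    profile = bin_profile(reads, fates, bin_width=bin_width)
    profile.to_frame().to_csv(out / "length_profile.tsv", sep="\t", index=False)
    return rls, asum, msum


# ---------------------------------------------------------------------------
# Monolithic run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages in order on the configured inputs.

    File-mediated staging makes this byte-identical to running the CLI
    subcommands one at a time on the same paths.  Returns the paths of the
    written outputs; also writes a run manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    stages = [
        ("map", lambda: map_stage(
            config.reads, config.reference, out / "candidates.tsv",
            config.params, config.policy)),
        ("filter", lambda: filter_stage(
            out / "candidates.tsv", config.reads, config.reference,
            config.repeats, out, config.params, config.policy)),
        ("call", lambda: call_stage(
            out / "placements.tsv", config.reads, config.reference, out)),
        ("report", lambda: report_stage(
            config.reads, out / "fates.tsv", out / "placements.tsv",
            out / "calls.tsv", config.reference, out,
            sample_name=config.sample_name, bin_width=config.bin_width,
            std_ddof=config.std_ddof, raw_wells=config.raw_wells,
            key_pass_wells=config.key_pass_wells)),
    ]
    for name, fn in stages:
        try:
            fn()
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {name}: {err}") from err

    manifest = {
        "version": __version__,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k not in ("params", "policy")},
            "params": dataclasses.asdict(config.params),
            "policy": {
                **dataclasses.asdict(config.policy),
                "recognized_classes": sorted(config.policy.recognized_classes),
            },
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "candidates": out / "candidates.tsv",
        "placements": out / "placements.tsv",
        "audit": out / "audit.tsv",
        "fates": out / "fates.tsv",
        "calls": out / "calls.tsv",
        "per_site": out / "per_site.tsv",
        "table1": out / "table1_read_lengths.tsv",
        "table2": out / "table2_alignment.tsv",
        "table3": out / "table3_methylation.tsv",
        "length_profile": out / "length_profile.tsv",
        "manifest": out / "manifest.json",
    }
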