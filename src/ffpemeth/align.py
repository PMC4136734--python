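"""Converted-space read mapping (pipeline step 1).

Both tagged versions of a read ('a': C->T, 'b': G->A) are aligned against
both strands of the phase-matched converted reference, giving four
(version x strand) combinations per read.  The alignment itself is an
exact affine-gap Smith-Waterman; for targets too large for a full dynamic
program, exact k-mer seeding selects candidate windows and the exact DP
runs inside each window.  All coordinates are reported on the Watson axis.

Default scoring (match 1, mismatch 3, gap open 5, gap extend 2, minimum
report score 30) mirrors the defaults of the classical long-read mapper
this pipeline's design is modelled on; the heuristic parameter ``z`` has
no effect on the exact DP and is only forwarded to the optional external
aligner adapter.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _sw
from .bisulfite import (
    CRICK,
    WATSON,
    ConvertedReference,
    TaggedRead,
    TAG_TO_PHASE,
)

_STRAND_RANK = {WATSON: 0, CRICK: 1}

# above this many DP cells the seeded-window path is used instead of full DP
FULL_DP_MAX_CELLS = 4_000_000
SEED_K = 16
SEED_STEP = 4
WINDOW_PAD = 32
MAX_WINDOWS = 16


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and reporting parameters for the local aligner."""

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 30
    unique_margin: int = 0
    z: int = 50  # opaque heuristic parameter, external adapter only

    def __post_init__(self) -> None:
        if self.mismatch <= 0 or self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("penalties must be positive")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment: score, half-open segment coordinates, op list."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ops: tuple[tuple[str, int], ...]

    @property
    def cigar(self) -> str:
        return "".join(f"{n}{c}" for c, n in self.ops)


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return tuple(ops)


def local_align(query: str, target: str, params: AlignmentParams) -> AlignmentHit:
    """Optimal affine-gap Smith-Waterman local alignment of query vs target.

    Deterministic traceback: best cell is the first maximum in (query
    position, target position) order; ties among moves prefer
    match/mismatch, then gap-in-target, then gap-in-query.
    A score of 0 means no positive-scoring local alignment exists.
    """
    if not query or not target:
        raise ValueError("local_align: empty query or target")
    score, qs, qe, ts, te, ops = _sw.sw_align(
        _sw.encode(query),
        _sw.encode(target),
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
    )
    return AlignmentHit(score, qs, qe, ts, te, tuple(ops))


@dataclass
class MappingResult:
    """One candidate placement of a tagged read (or fragment) on the genome.

    Coordinates ``ref_start``/``ref_end`` are 0-based half-open on the
    Watson axis regardless of the mapped strand.  ``read_start``/``read_end``
    are within the query (the fragment, for split reads); ``frag_offset``
    locates the fragment within the parent read.  ``read_bases`` are the
    query's ORIGINAL (unconverted) bases -- the methylation signal.
    """

    read_id: str  # parent read id
    query_id: str  # read id, or read id + split suffix
    tag: str  # 'a' or 'b'
    contig: str
    strand: str  # Watson | Crick
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: int
    cigar: str
    read_bases: str  # original bases of the whole query
    contig_length: int
    frag_offset: int = 0
    repeat_marks: dict[int, str] = field(default_factory=dict)
    repeat_overlap_bp: int = 0
    unique: bool = False

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("ref_end must be > ref_start")

    @property
    def ops(self) -> tuple[tuple[str, int], ...]:
        return parse_cigar(self.cigar)

    @property
    def aligned_length(self) -> int:
        """Number of 'M'-flagged (aligned, non-gap) read positions."""
        return sum(n for c, n in self.ops if c == "M")

    def aligned_pairs(self):
        """Yield (query_pos, watson_pos) for every 'M'-flagged position.

        ``query_pos`` indexes the query in its own orientation;
        ``watson_pos`` is the 0-based Watson-axis reference coordinate.
        """
        q = self.read_start
        if self.strand == WATSON:
            t = self.ref_start
            for c, n in self.ops:
                if c == "M":
                    for k in range(n):
                        yield q + k, t + k
                    q += n
                    t += n
                elif c == "I":
                    q += n
                else:
                    t += n
        else:
            # target axis is the Crick sequence; strand position ts maps to
            # Watson position L-1-ts
            t = self.contig_length - self.ref_end
            for c, n in self.ops:
                if c == "M":
                    for k in range(n):
                        yield q + k, self.contig_length - 1 - (t + k)
                    q += n
                    t += n
                elif c == "I":
                    q += n
                else:
                    t += n

    def m_read_positions(self) -> list[int]:
        return [q for q, _ in self.aligned_pairs()]

    def m_watson_positions(self) -> set[tuple[str, int]]:
        return {(self.contig, w) for _, w in self.aligned_pairs()}

    def sort_key(self):
        """Deterministic placement order: score desc, then position/strand/tag."""
        return (
            -self.score,
            self.contig,
            self.ref_start,
            _STRAND_RANK[self.strand],
            self.tag,
        )


class SeedIndex:
    """Exact k-mer index over the four converted reference sequences."""

    def __init__(self, ref: ConvertedReference, k: int = SEED_K):
        self.k = k
        self._index: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
        for contig in ref.contigs:
            for strand in (WATSON, CRICK):
                for phase in ("ct", "ga"):
                    seq = ref.get(contig, strand, phase)
                    table: dict[str, list[int]] = {}
                    for i in range(0, len(seq) - k + 1):
                        kmer = seq[i : i + k]
                        table.setdefault(kmer, []).append(i)
                    self._index[(contig, strand, phase)] = {
                        km: np.asarray(pos, dtype=np.int64)
                        for km, pos in table.items()
                    }

    def windows(self, query: str, contig: str, strand: str, phase: str,
                target_len: int) -> list[tuple[int, int]]:
        """Candidate target windows for a query, from clustered seed diagonals."""
        table = self._index[(contig, strand, phase)]
        k = self.k
        qlen = len(query)
        hits: list[tuple[int, int]] = []  # (diagonal, target pos)
        for qpos in range(0, max(qlen - k, 0) + 1, SEED_STEP):
            kmer = query[qpos : qpos + k]
            pos = table.get(kmer)
            if pos is not None:
                for tpos in pos:
                    hits.append((int(tpos) - qpos, int(tpos)))
        if not hits:
            return []
        hits.sort()
        clusters: list[list[tuple[int, int]]] = [[hits[0]]]
        for h in hits[1:]:
            if h[0] - clusters[-1][-1][0] <= WINDOW_PAD:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        clusters.sort(key=lambda c: (-len(c), c[0][0]))
        windows = []
        for cluster in clusters[:MAX_WINDOWS]:
            diags = [d for d, _ in cluster]
            lo = max(0, min(diags) - WINDOW_PAD)
            hi = min(target_len, max(diags) + qlen + WINDOW_PAD)
            if hi > lo:
                windows.append((lo, hi))
        # merge overlapping windows
        windows.sort()
        merged = [windows[0]]
        for lo, hi in windows[1:]:
            if lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged


# the four (version x strand) mapping combinations; phase follows the tag
_COMBOS = (("a", WATSON), ("a", CRICK), ("b", WATSON), ("b", CRICK))


def map_tagged_read(
    version_a: TaggedRead,
    version_b: TaggedRead,
    ref: ConvertedReference,
    params: AlignmentParams,
    seed_index: SeedIndex | None = None,
    query_id: str | None = None,
    parent_id: str | None = None,
    frag_offset: int = 0,
) -> list[MappingResult]:
    """Map both tagged versions of one read to both converted strands.

    Returns candidate placements with score >= ``params.min_score``, sorted
    by the aligner's deterministic order (score descending, then contig,
    Watson start, Watson before Crick, tag 'a' before 'b').  An empty list
    means unmapped.
    """
    read = version_a.read
    qid = query_id if query_id is not None else read.id
    pid = parent_id if parent_id is not None else read.id
    results: list[MappingResult] = []
    seen: set[tuple] = set()
    for tag, strand in _COMBOS:
        version = version_a if tag == "a" else version_b
        query = version.converted_bases
        phase = TAG_TO_PHASE[tag]
        for contig in ref.contigs:
            target = ref.get(contig, strand, phase)
            tlen = len(target)
            if seed_index is not None and len(query) * tlen > FULL_DP_MAX_CELLS:
                windows = seed_index.windows(query, contig, strand, phase, tlen)
            else:
                windows = [(0, tlen)]
            for wlo, whi in windows:
                hit = local_align(query, target[wlo:whi], params)
                if hit.score < params.min_score:
                    continue
                ts = wlo + hit.t_start
                te = wlo + hit.t_end
                if strand == WATSON:
                    ref_start, ref_end = ts, te
                else:
                    ref_start, ref_end = tlen - te, tlen - ts
                key = (tag, contig, strand, ref_start, ref_end,
                       hit.q_start, hit.q_end)
                if key in seen:
                    continue
                seen.add(key)
                results.append(
                    MappingResult(
                        read_id=pid,
                        query_id=qid,
                        tag=tag,
                        contig=contig,
                        strand=strand,
                        ref_start=ref_start,
                        ref_end=ref_end,
                        read_start=hit.q_start,
                        read_end=hit.q_end,
                        score=hit.score,
                        cigar=hit.cigar,
                        read_bases=read.bases,
                        contig_length=tlen,
                        frag_offset=frag_offset,
                    )
                )
    results.sort(key=MappingResult.sort_key)
    return results


# ---------------------------------------------------------------------------
# Optional external aligner adapter
# ---------------------------------------------------------------------------


class ExternalAlignerError(RuntimeError):
    """The external aligner feature was requested but is unavailable."""


def external_aligner_adapter(
    reads_fasta: str | Path,
    ref_fasta: str | Path,
    params: AlignmentParams,
    workdir: str | Path,
    tag: str,
    strand: str,
    contig_lengths: dict[str, int],
    executable: str = "bwa",
) -> list[MappingResult]:
    """Map converted reads with an external BWA-SW binary (off by default).

    ``reads_fasta`` must hold phase-converted reads and ``ref_fasta`` the
    matching phase-converted reference strand; only forward-strand SAM hits
    are kept so the (version x strand) semantics match the internal path.
    The heuristic parameter ``z`` is forwarded.  A missing binary raises
    :class:`ExternalAlignerError` -- never a silent fallback.
    """
    import pysam

    if shutil.which(executable) is None:
        raise ExternalAlignerError(
            f"external aligner {executable!r} not found on PATH"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref_local = workdir / Path(ref_fasta).name
    if ref_local.resolve() != Path(ref_fasta).resolve():
        shutil.copy(ref_fasta, ref_local)
    subprocess.run(
        [executable, "index", str(ref_local)],
        check=True, capture_output=True,
    )
    sam_path = workdir / "external_hits.sam"
    with open(sam_path, "wb") as out:
        subprocess.run(
            [
                executable, "bwasw",
                "-z", str(params.z),
                "-T", str(params.min_score),
                str(ref_local), str(reads_fasta),
            ],
            check=True, stdout=out, stderr=subprocess.DEVNULL,
        )
    results: list[MappingResult] = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_reverse:
                continue
            contig = rec.reference_name
            tlen = contig_lengths[contig]
            ts, te = rec.reference_start, rec.reference_end
            if strand == WATSON:
                ref_start, ref_end = ts, te
            else:
                ref_start, ref_end = tlen - te, tlen - ts
            op_map = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}
            cigar = "".join(
                f"{length}{op_map[op]}"
                for op, length in rec.cigartuples
                if op in op_map
            )
            qstart = rec.query_alignment_start
            qend = rec.query_alignment_end
            results.append(
                MappingResult(
                    read_id=rec.query_name,
                    query_id=rec.query_name,
                    tag=tag,
                    contig=contig,
                    strand=strand,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    read_start=qstart,
                    read_end=qend,
                    score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                    cigar=cigar,
                    read_bases=rec.query_sequence or "",
                    contig_length=tlen,
                )
            )
    results.sort(key=MappingResult.sort_key)
    return results
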