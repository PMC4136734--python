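"""Repeat marking, placement filtering and read splitting (steps 2-4).

Step 2 marks aligned read positions that fall inside recognized repeat
classes and removes placements that span two distinct repeat types or
retain too little unmarked aligned sequence.  Step 3 resolves
multi-mapping within one (read, version) pair by minimal repeat overlap,
then reconciles the surviving 'a' and 'b' placements of the same read by
reference-coverage containment/overlap rules.  Step 4 splits reads that
ended up with no surviving placement and sends the fragments back through
steps 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree

from .align import MappingResult
from .seq_io import RawRead, RepeatInterval

#: repeat classes the removal rules recognize (labels matched verbatim)
RECOGNIZED_CLASSES = frozenset(
    {
        "Alu",
        "simple repeats",
        "ERVL-MaLR",
        "low-complexity",
        "L1HS",
        "L1M",
        "L1P",
        "LTR ERV",
        "Segmental Dups",
        "CNVs",
    }
)

REASON_TWO_REPEAT_TYPES = "two-repeat-types"
REASON_SHORT_UNMARKED_M = "short-unmarked-M"
REASON_MULTIMAP = "multimap-longer-repeat-overlap"
REASON_CONTAINED = "contained-by-other-version"
REASON_SHORT_RESIDUAL = "short-residual-overlap"
REASON_SHORT_READ = "short-read"


@dataclass(frozen=True)
class RepeatPolicy:
    """Thresholds and class set for the repeat/overlap filters.

    ``min_unmarked_m``: minimum unmarked aligned ('M') bp a placement must
    keep (default 20).  ``overlap_residual``: maximum non-overlapped 'M' bp
    at which a partly-overlapped placement is removed (default 20).
    ``remap_min_len``: minimum read/fragment length eligible for repeated
    mapping (default 35).  ``min_read_len``: reads shorter than this are
    dropped before mapping (default 40).
    """

    recognized_classes: frozenset[str] = RECOGNIZED_CLASSES
    min_unmarked_m: int = 20
    overlap_residual: int = 20
    remap_min_len: int = 35
    min_read_len: int = 40
    max_split_rounds: int = 2

    def __post_init__(self) -> None:
        if min(self.min_unmarked_m, self.overlap_residual,
               self.remap_min_len, self.min_read_len) <= 0:
            raise ValueError("thresholds must be positive")

    def with_extra_classes(self, classes: Iterable[str]) -> "RepeatPolicy":
        """Return a policy whose recognized set includes extra labels."""
        return RepeatPolicy(
            recognized_classes=self.recognized_classes | frozenset(classes),
            min_unmarked_m=self.min_unmarked_m,
            overlap_residual=self.overlap_residual,
            remap_min_len=self.remap_min_len,
            min_read_len=self.min_read_len,
            max_split_rounds=self.max_split_rounds,
        )


class RepeatIndex:
    """Interval lookup over the merged repeat annotation (all classes)."""

    def __init__(self, intervals: Iterable[RepeatInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.contig, IntervalTree()).addi(
                iv.start, iv.end, iv.repeat_class
            )

    def classes_at(self, contig: str, pos: int) -> list[str]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(pos))

    def covered(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        return tree is not None and bool(tree.at(pos))


class FilterDecision(NamedTuple):
    keep: bool
    reason: str | None


def mark_repeats(m: MappingResult, repeats: RepeatIndex,
                 policy: RepeatPolicy) -> MappingResult:
    """Mark aligned read positions overlapping recognized repeat classes.

    Also records the total repeat overlap in bp (any class, recognized or
    not) used later by multi-mapping resolution.  Mutates and returns
    ``m``.
    """
    marks: dict[int, str] = {}
    overlap = 0
    for qpos, wpos in m.aligned_pairs():
        classes = repeats.classes_at(m.contig, wpos)
        if classes:
            overlap += 1
            recognized = [c for c in classes if c in policy.recognized_classes]
            if recognized:
                marks[qpos] = recognized[0]  # lexicographically smallest
    m.repeat_marks = marks
    m.repeat_overlap_bp = overlap
    return m


def distinct_repeat_classes(m: MappingResult) -> set[str]:
    return set(m.repeat_marks.values())


def unmarked_m_length(m: MappingResult) -> int:
    return m.aligned_length - len(m.repeat_marks)


def filter_repeat_hit(m: MappingResult, policy: RepeatPolicy) -> FilterDecision:
    """Step-2 removal rules for a marked placement.

    Remove if the placement spans two different recognized repeat types, or
    if its unmarked aligned length is below ``policy.min_unmarked_m``.
    """
    if len(distinct_repeat_classes(m)) >= 2:
        return FilterDecision(False, REASON_TWO_REPEAT_TYPES)
    if unmarked_m_length(m) < policy.min_unmarked_m:
        return FilterDecision(False, REASON_SHORT_UNMARKED_M)
    return FilterDecision(True, None)


def resolve_multimapping(
    hits: list[MappingResult],
) -> tuple[MappingResult | None, list[MappingResult]]:
    """Keep the placement with the shortest repeat overlap (step 3, part 1).

    ``hits`` must all belong to one (read, version) pair.  Ties are broken
    by the aligner's deterministic order (score descending, then contig,
    Watson start, strand, tag).  Returns (kept, removed).
    """
    if not hits:
        return None, []
    ranked = sorted(hits, key=lambda h: (h.repeat_overlap_bp, *h.sort_key()))
    return ranked[0], ranked[1:]


def resolve_version_overlap(
    a_hit: MappingResult | None,
    b_hit: MappingResult | None,
    policy: RepeatPolicy,
) -> tuple[list[MappingResult], list[tuple[MappingResult, str]], bool]:
    """Reconcile the surviving 'a' and 'b' placements of one read (step 3).

    Containment of one placement's aligned reference positions by the
    other's removes the contained one (equal coverage: the lower-scoring
    one is removed, tie removes 'b' -- the higher-scoring placement carries
    the true conversion phase).  Partial overlap with a non-overlapped 'M'
    residue of at most ``policy.overlap_residual`` bp removes that
    placement; if both qualify only the lower-scoring one is removed.

    Returns (survivors, [(removed, reason)...], disjoint_loci_flag); the
    flag marks the undecided case of both versions surviving at disjoint
    loci.
    """
    if a_hit is None and b_hit is None:
        return [], [], False
    if b_hit is None:
        return [a_hit], [], False
    if a_hit is None:
        return [b_hit], [], False

    pos_a = a_hit.m_watson_positions()
    pos_b = b_hit.m_watson_positions()
    shared = pos_a & pos_b
    if not shared:
        return [a_hit, b_hit], [], True

    a_in_b = pos_a <= pos_b
    b_in_a = pos_b <= pos_a
    if a_in_b and b_in_a:  # identical coverage: keep the better score
        loser = b_hit if b_hit.score <= a_hit.score else a_hit
        winner = a_hit if loser is b_hit else b_hit
        return [winner], [(loser, REASON_CONTAINED)], False
    if b_in_a:
        return [a_hit], [(b_hit, REASON_CONTAINED)], False
    if a_in_b:
        return [b_hit], [(a_hit, REASON_CONTAINED)], False

    resid_a = len(pos_a - pos_b)
    resid_b = len(pos_b - pos_a)
    a_removable = resid_a <= policy.overlap_residual
    b_removable = resid_b <= policy.overlap_residual
    if a_removable and b_removable:
        loser = b_hit if b_hit.score <= a_hit.score else a_hit
        winner = a_hit if loser is b_hit else b_hit
        return [winner], [(loser, REASON_SHORT_RESIDUAL)], False
    if b_removable:
        return [a_hit], [(b_hit, REASON_SHORT_RESIDUAL)], False
    if a_removable:
        return [b_hit], [(a_hit, REASON_SHORT_RESIDUAL)], False
    return [a_hit, b_hit], [], False


def split_read(read: RawRead, policy: RepeatPolicy,
               base_id: str | None = None) -> list[tuple[str, int, RawRead]]:
    """Split a read at its midpoint into fragments for repeated mapping.

    Returns (fragment_id, offset_in_parent, fragment_read) triples;
    fragments shorter than ``policy.remap_min_len`` are discarded.
    """
    bid = base_id if base_id is not None else read.id
    mid = len(read) // 2
    out = []
    for part, (lo, hi) in enumerate(((0, mid), (mid, len(read)))):
        if hi - lo >= policy.remap_min_len:
            frag_id = f"{bid}|s{part}"
            qual = read.quality[lo:hi] if read.quality is not None else None
            out.append((frag_id, lo, RawRead(frag_id, read.bases[lo:hi], qual)))
    return out
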