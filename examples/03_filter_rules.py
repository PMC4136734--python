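"""Walk through the repeat and overlap filter rules on constructed placements.

Degraded-sample reads land disproportionately in repeats, where
placements are unreliable.  The filter removes a placement that (1) spans
two different repeat classes, or (2) keeps fewer than 20 unmarked aligned
bp; among multiple placements of one read version only the one with the
shortest repeat overlap survives; and the 'a'/'b' versions of the same
read are reconciled by containment / residual-overlap rules.
"""

from ffpemeth import (
    MappingResult,
    RepeatIndex,
    RepeatInterval,
    RepeatPolicy,
    mark_repeats,
    resolve_multimapping,
    resolve_version_overlap,
)
from ffpemeth.filters import filter_repeat_hit

policy = RepeatPolicy()


def placement(start, end, tag="a"):
    n = end - start
    return MappingResult(
        read_id="r", query_id="r", tag=tag, contig="chr1", strand="Watson",
        ref_start=start, ref_end=end, read_start=0, read_end=n, score=n,
        cigar=f"{n}M", read_bases="A" * n, contig_length=10_000,
    )


repeats = RepeatIndex([
    RepeatInterval("chr1", 100, 130, "Alu"),
    RepeatInterval("chr1", 140, 160, "L1M"),
    RepeatInterval("chr1", 500, 545, "Alu"),
])

m = mark_repeats(placement(100, 160), repeats, policy)
keep, reason = filter_repeat_hit(m, policy)
print(f"placement 100-160 spans Alu and L1M  -> keep={keep} ({reason})")

m = mark_repeats(placement(500, 560), repeats, policy)
keep, reason = filter_repeat_hit(m, policy)
print(f"placement 500-560, 45/60 bp in Alu   -> keep={keep} ({reason})")

m = mark_repeats(placement(505, 565), repeats, policy)
keep, reason = filter_repeat_hit(m, policy)
print(f"placement 505-565, 40/60 bp in Alu   -> keep={keep} (unmarked 20 >= 20)")

a = mark_repeats(placement(100, 160), repeats, policy)
b = mark_repeats(placement(9000, 9060), repeats, policy)
kept, removed = resolve_multimapping([a, b])
print(
    f"\nmulti-mapping: overlaps {a.repeat_overlap_bp} bp vs "
    f"{b.repeat_overlap_bp} bp -> keep the placement at "
    f"{kept.ref_start}-{kept.ref_end}"
)

survivors, removed, _ = resolve_version_overlap(
    placement(100, 200, tag="a"), placement(185, 215, tag="b"), policy
)
print(
    "\nversion overlap: 'b' (185-215) leaves only 15 bp outside 'a' "
    f"(100-200) -> survivors: {[f'{m.tag}:{m.ref_start}-{m.ref_end}' for m in survivors]}"
)
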