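import itertools
import random

from ffpemeth import (
    MappingResult,
    RawRead,
    RepeatIndex,
    RepeatInterval,
    build_converted_reference,
    convert_ct,
    make_tagged_versions,
    map_tagged_read,
    mark_repeats,
    resolve_multimapping,
    resolve_version_overlap,
    split_read,
)
from ffpemeth.filters import (
    REASON_CONTAINED,
    REASON_SHORT_RESIDUAL,
    REASON_SHORT_UNMARKED_M,
    REASON_TWO_REPEAT_TYPES,
    filter_repeat_hit,
)
from ffpemeth.seq_io import ReferenceGenome

from conftest import random_sequence


def placement(start, end, tag="a", score=None, read_id="r", contig="chr1",
              strand="Watson", contig_length=10_000):
    length = end - start
    return MappingResult(
        read_id=read_id, query_id=read_id, tag=tag, contig=contig,
        strand=strand, ref_start=start, ref_end=end, read_start=0,
        read_end=length, score=score if score is not None else length,
        cigar=f"{length}M", read_bases="A" * length, contig_length=contig_length,
    )


def index_of(*intervals):
    return RepeatIndex([RepeatInterval("chr1", s, e, c) for s, e, c in intervals])


class TestMarkRepeats:
    def test_single_interval_marks_overlap(self, policy):
        m = mark_repeats(placement(100, 160), index_of((120, 140, "Alu")), policy)
        assert len(m.repeat_marks) == 20
        assert set(m.repeat_marks.values()) == {"Alu"}

    def test_no_overlap_no_marks(self, policy):
        m = mark_repeats(placement(100, 160), index_of((300, 400, "Alu")), policy)
        assert m.repeat_marks == {} and m.repeat_overlap_bp == 0

    def test_two_classes_recorded(self, policy):
        m = mark_repeats(
            placement(100, 160),
            index_of((100, 130, "Alu"), (140, 160, "L1M")),
            policy,
        )
        assert set(m.repeat_marks.values()) == {"Alu", "L1M"}

    def test_unrecognized_class_counts_for_overlap_only(self, policy):
        m = mark_repeats(placement(100, 160), index_of((120, 140, "MIR")), policy)
        assert m.repeat_marks == {}
        assert m.repeat_overlap_bp == 20


class TestRepeatRemovalRules:
    def test_two_repeat_types_removed(self, policy):
        m = mark_repeats(
            placement(100, 160),
            index_of((100, 130, "Alu"), (140, 160, "L1M")),
            policy,
        )
        assert filter_repeat_hit(m, policy) == (False, REASON_TWO_REPEAT_TYPES)

    def test_short_unmarked_m_removed(self, policy):
        # 60 aligned, 45 marked by one class: unmarked 15 < 20
        m = mark_repeats(placement(100, 160), index_of((100, 145, "Alu")), policy)
        assert filter_repeat_hit(m, policy) == (False, REASON_SHORT_UNMARKED_M)

    def test_enough_unmarked_kept(self, policy):
        # 60 aligned, 30 marked: unmarked 30 >= 20
        m = mark_repeats(placement(100, 160), index_of((100, 130, "Alu")), policy)
        assert filter_repeat_hit(m, policy) == (True, None)


class TestResolveMultimapping:
    def test_shortest_overlap_wins(self, policy):
        a = mark_repeats(placement(100, 160), index_of((100, 125, "Alu")), policy)
        b = mark_repeats(placement(500, 560), index_of((500, 505, "Alu")), policy)
        kept, removed = resolve_multimapping([a, b])
        assert kept is b and removed == [a]

    def test_single_placement_kept(self):
        m = placement(100, 160)
        kept, removed = resolve_multimapping([m])
        assert kept is m and removed == []

    def test_tie_break_is_order_independent(self, policy):
        # overlaps 10/10/40: the winner among the tied 10s must not depend
        # on input order; enumerate all orderings against the first run
        hits = []
        for start, rep_end in ((100, 110), (500, 510), (900, 940)):
            m = mark_repeats(
                placement(start, start + 60),
                index_of((start, rep_end, "Alu")),
                policy,
            )
            hits.append(m)
        baseline = resolve_multimapping(list(hits))[0]
        for perm in itertools.permutations(hits):
            assert resolve_multimapping(list(perm))[0] is baseline
        assert baseline.ref_start == 100  # lowest start among the tie

    def test_at_most_one_survivor(self):
        hits = [placement(i * 100, i * 100 + 60) for i in range(5)]
        kept, removed = resolve_multimapping(hits)
        assert kept is not None and len(removed) == 4


class TestResolveVersionOverlap:
    def test_total_containment_removes_covered(self, policy):
        a = placement(100, 200, tag="a")
        b = placement(120, 180, tag="b")
        survivors, removed, disjoint = resolve_version_overlap(a, b, policy)
        assert survivors == [a]
        assert removed == [(b, REASON_CONTAINED)]
        assert not disjoint

    def test_long_residual_both_survive(self, policy):
        a = placement(100, 200, tag="a")
        b = placement(185, 260, tag="b")  # residual 60 > 20
        survivors, removed, _ = resolve_version_overlap(a, b, policy)
        assert survivors == [a, b] and removed == []

    def test_short_residual_removed(self, policy):
        a = placement(100, 200, tag="a")
        b = placement(185, 215, tag="b")  # residual 15 <= 20
        survivors, removed, _ = resolve_version_overlap(a, b, policy)
        assert survivors == [a]
        assert removed == [(b, REASON_SHORT_RESIDUAL)]

    def test_disjoint_loci_both_survive_flagged(self, policy):
        a = placement(100, 200, tag="a")
        b = placement(5000, 5100, tag="b")
        survivors, removed, disjoint = resolve_version_overlap(a, b, policy)
        assert survivors == [a, b] and disjoint

    def test_identical_coverage_keeps_higher_score(self, policy):
        a = placement(100, 200, tag="a", score=95)
        b = placement(100, 200, tag="b", score=40)
        survivors, removed, _ = resolve_version_overlap(a, b, policy)
        assert survivors == [a] and removed[0][0] is b
        # and the reverse: a wrong-phase 'a' must lose to a true-phase 'b'
        a2 = placement(100, 200, tag="a", score=40)
        b2 = placement(100, 200, tag="b", score=95)
        survivors, removed, _ = resolve_version_overlap(a2, b2, policy)
        assert survivors == [b2] and removed[0][0] is a2

    def test_missing_side_passes_through(self, policy):
        a = placement(100, 200, tag="a")
        assert resolve_version_overlap(a, None, policy)[0] == [a]
        assert resolve_version_overlap(None, a, policy)[0] == [a]


class TestSplitAndRemap:
    def test_midpoint_split(self, policy):
        frags = split_read(RawRead("r", "A" * 80), policy)
        assert [(fid, off, len(fr)) for fid, off, fr in frags] == [
            ("r|s0", 0, 40),
            ("r|s1", 40, 40),
        ]

    def test_short_read_yields_nothing(self, policy):
        assert split_read(RawRead("r", "A" * 30), policy) == []

    def test_uneven_split_keeps_long_half(self, policy):
        # 75 bp -> halves of 37 and 38; both >= 35 survive
        frags = split_read(RawRead("r", "A" * 75), policy)
        assert [len(fr) for _, _, fr in frags] == [37, 38]

    def test_planted_chimera_recovered_after_split(self, params, policy):
        rng = random.Random(8)
        genome = ReferenceGenome({"chr1": random_sequence(rng, 4_000)})
        ref = build_converted_reference(genome)
        left = convert_ct(genome["chr1"][500:550])
        right = convert_ct(genome["chr1"][3000:3050])
        chimera = RawRead("chimera", left + right)
        loci = []
        for frag_id, off, frag in split_read(chimera, policy):
            a, b = make_tagged_versions(frag)
            hits = map_tagged_read(a, b, ref, params, query_id=frag_id,
                                   parent_id="chimera", frag_offset=off)
            loci.append((hits[0].ref_start, hits[0].ref_end))
        assert loci == [(500, 550), (3000, 3050)]
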