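import math

import pytest

from ffpemeth import (
    CPA,
    CPG,
    CytosineSite,
    MappingResult,
    MethylationCall,
    build_converted_reference,
    call_methylation,
    context_methylation_rate,
    conversion_rate,
    coverage_stats,
    smp_rate,
    symmetric_asymmetric_rates,
)
from ffpemeth.bisulfite import CRICK, WATSON
from ffpemeth.methylation import (
    METHYLATED,
    UNINFORMATIVE,
    UNMETHYLATED,
    site_context,
)
from ffpemeth.seq_io import ReferenceGenome


def placement(contig_len, bases, tag, strand, ref_start=None, ref_end=None,
              read_id="r", unique=False, contig="c"):
    n = len(bases)
    if strand == WATSON:
        start = 0 if ref_start is None else ref_start
        end = start + n
    else:
        end = contig_len if ref_end is None else ref_end
        start = end - n
    return MappingResult(
        read_id=read_id, query_id=read_id, tag=tag, contig=contig,
        strand=strand, ref_start=start, ref_end=end, read_start=0,
        read_end=n, score=n, cigar=f"{n}M", read_bases=bases,
        contig_length=contig_len, unique=unique,
    )


def call(state, context=CPG, strand=WATSON, pos=2, read_id="r", contig="c"):
    return MethylationCall(CytosineSite(contig, pos, strand, context), read_id, state)


class TestCallMethylation:
    def test_hand_worked_seven_mer(self):
        # reference TACGTCA: CpG cytosine at 2, CpA cytosine at 5 (Watson);
        # read retains C at the CpG (methylated), converted T at the CpA
        genome = ReferenceGenome({"c": "TACGTCA"})
        m = placement(7, "TACGTTA", "a", WATSON)
        calls = call_methylation([m], genome)
        by_pos = {c.site.pos: c for c in calls}
        assert set(by_pos) == {2, 5}
        assert by_pos[2].site.context == CPG and by_pos[2].state == METHYLATED
        assert by_pos[5].site.context == CPA and by_pos[5].state == UNMETHYLATED

    def test_n_over_site_is_uninformative(self):
        genome = ReferenceGenome({"c": "TACGTCA"})
        m = placement(7, "TANGTTA", "a", WATSON)
        calls = {c.site.pos: c for c in call_methylation([m], genome)}
        assert calls[2].state == UNINFORMATIVE

    def test_window_without_cytosines_gives_no_calls(self):
        genome = ReferenceGenome({"c": "TATATATA"})
        m = placement(8, "TATATATA", "a", WATSON)
        assert call_methylation([m], genome) == []

    def test_out_of_contig_placement_is_error(self):
        genome = ReferenceGenome({"c": "ACGT"})
        m = placement(100, "A" * 10, "a", WATSON, ref_start=96)
        m.contig_length = 4
        with pytest.raises(ValueError, match="outside contig"):
            call_methylation([m], genome)

    def test_all_four_strand_state_readouts(self):
        # genome AACGTT: CpG dyad with Watson C at 2 and Crick C at 3;
        # revcomp(AACGTT) == AACGTT, so every template reads AACGTT and a
        # fully methylated site retains its C (or G) in each phase
        genome = ReferenceGenome({"c": "AACGTT"})
        cases = [
            ("a", WATSON, WATSON, 2),  # direct Watson readout
            ("b", WATSON, CRICK, 3),  # complement-of-Crick readout
            ("a", CRICK, CRICK, 3),  # direct Crick readout
            ("b", CRICK, WATSON, 2),  # complement-of-Watson readout
        ]
        for tag, strand, site_strand, pos in cases:
            m = placement(6, "AACGTT", tag, strand)
            calls = call_methylation([m], genome)
            assert len(calls) == 1, (tag, strand)
            c = calls[0]
            assert (c.site.strand, c.site.pos) == (site_strand, pos)
            assert c.site.context == CPG
            assert c.state == METHYLATED

    def test_converted_reads_are_unmethylated(self):
        genome = ReferenceGenome({"c": "AACGTT"})
        m = placement(6, "AATGTT", "a", WATSON)  # C->T converted
        assert call_methylation([m], genome)[0].state == UNMETHYLATED
        m = placement(6, "AACATT", "b", WATSON)  # G->A converted
        assert call_methylation([m], genome)[0].state == UNMETHYLATED

    def test_call_states_partition(self):
        genome = ReferenceGenome({"c": "CCGGCCGG"})
        m = placement(8, "CTNGCCGA", "a", WATSON)
        calls = call_methylation([m], genome)
        states = [c.state for c in calls]
        assert len(calls) == sum(
            states.count(s) for s in (METHYLATED, UNMETHYLATED, UNINFORMATIVE)
        )


class TestSiteContext:
    def test_watson_contexts(self):
        genome = ReferenceGenome({"c": "ACGCATCT"})
        assert site_context(genome, "c", 1, WATSON) == CPG
        assert site_context(genome, "c", 3, WATSON) == CPA
        assert site_context(genome, "c", 5, WATSON) == "other"
        assert site_context(genome, "c", 7, WATSON) == "other"  # contig edge

    def test_crick_contexts(self):
        # Crick C sits at a Watson G; its next base is the complement of
        # the preceding Watson base
        genome = ReferenceGenome({"c": "CGTGAG"})
        assert site_context(genome, "c", 1, CRICK) == CPG  # preceded by C
        assert site_context(genome, "c", 3, CRICK) == CPA  # preceded by T
        assert site_context(genome, "c", 5, CRICK) == "other"


class TestConversionRate:
    def test_simple_quotient(self):
        calls = [call(UNMETHYLATED, context=CPA, pos=i) for i in range(97)]
        calls += [call(METHYLATED, context=CPA, pos=100 + i) for i in range(3)]
        cr = conversion_rate(calls)
        assert cr.percent_converted == pytest.approx(97.0)

    def test_all_converted_is_100(self):
        calls = [call(UNMETHYLATED, context="other", pos=i) for i in range(10)]
        assert conversion_rate(calls).percent_converted == 100.0

    def test_cpg_calls_excluded(self):
        calls = [call(METHYLATED, context=CPG, pos=i) for i in range(50)]
        assert math.isnan(conversion_rate(calls).percent_converted)

    def test_literal_quotient_is_complement(self):
        calls = [call(UNMETHYLATED, context=CPA, pos=i) for i in range(7)]
        calls += [call(METHYLATED, context=CPA, pos=10 + i) for i in range(3)]
        cr = conversion_rate(calls)
        assert cr.percent_converted + cr.percent_unconverted == pytest.approx(100.0)


class TestContextRate:
    def test_pooled_percentage(self):
        calls = [
            call(METHYLATED, pos=2), call(METHYLATED, pos=2, read_id="r2"),
            call(UNMETHYLATED, pos=10),
        ]
        assert context_methylation_rate(calls, CPG, WATSON) == pytest.approx(66.67, abs=0.01)

    def test_zero_methylated(self):
        calls = [call(UNMETHYLATED, pos=i) for i in range(5)]
        assert context_methylation_rate(calls, CPG, WATSON) == 0.0

    def test_no_informative_calls_is_nan(self):
        calls = [call(UNINFORMATIVE)]
        assert math.isnan(context_methylation_rate(calls, CPG, WATSON))

    def test_strand_and_context_filtering(self):
        calls = [call(METHYLATED, strand=CRICK), call(UNMETHYLATED, context=CPA)]
        assert math.isnan(context_methylation_rate(calls, CPG, WATSON))
        assert context_methylation_rate(calls, CPG, CRICK) == 100.0


class TestSmpRate:
    def test_mixed_site_fraction(self):
        calls = []
        for site_idx in range(10):  # 10 eligible sites, first 3 mixed
            pos = site_idx * 10
            first = METHYLATED if site_idx < 3 else UNMETHYLATED
            calls.append(call(first, pos=pos, read_id="r1"))
            calls.append(call(UNMETHYLATED, pos=pos, read_id="r2"))
        assert smp_rate(calls, CPG)[WATSON] == pytest.approx(30.0)

    def test_homogeneous_sites_are_zero(self):
        calls = [call(METHYLATED, pos=0, read_id=f"r{i}") for i in range(4)]
        assert smp_rate(calls, CPG)[WATSON] == 0.0

    def test_cct_site_counts_as_mixed(self):
        calls = [
            call(METHYLATED, read_id="r1"),
            call(METHYLATED, read_id="r2"),
            call(UNMETHYLATED, read_id="r3"),
        ]
        assert smp_rate(calls, CPG)[WATSON] == 100.0

    def test_low_coverage_is_nan(self):
        assert math.isnan(smp_rate([call(METHYLATED)], CPG)[WATSON])


class TestSymmetricAsymmetric:
    def _dyad(self, pos, watson_state, crick_state):
        return [
            call(watson_state, pos=pos, strand=WATSON),
            call(crick_state, pos=pos + 1, strand=CRICK),
        ]

    def test_single_symmetric_dyad(self):
        calls = self._dyad(0, METHYLATED, METHYLATED)
        assert symmetric_asymmetric_rates(calls) == (100.0, 0.0)

    def test_single_asymmetric_dyad(self):
        calls = self._dyad(0, METHYLATED, UNMETHYLATED)
        assert symmetric_asymmetric_rates(calls) == (0.0, 100.0)

    def test_mixture_of_dyads(self):
        calls = (
            self._dyad(0, METHYLATED, METHYLATED)
            + self._dyad(10, METHYLATED, METHYLATED)
            + self._dyad(20, METHYLATED, UNMETHYLATED)
            + self._dyad(30, UNMETHYLATED, UNMETHYLATED)
        )
        sym, asym = symmetric_asymmetric_rates(calls)
        assert (sym, asym) == (50.0, 25.0)

    def test_tie_counts_as_unmethylated(self):
        calls = self._dyad(0, METHYLATED, METHYLATED)
        calls.append(call(UNMETHYLATED, pos=0, strand=WATSON, read_id="r2"))
        sym, asym = symmetric_asymmetric_rates(calls)  # Watson tied 1:1
        assert (sym, asym) == (0.0, 100.0)

    def test_no_eligible_dyad_is_nan(self):
        sym, asym = symmetric_asymmetric_rates([call(METHYLATED)])
        assert math.isnan(sym) and math.isnan(asym)


class TestCoverageStats:
    def _genome(self, n=1000):
        return ReferenceGenome({"c": "AT" * (n // 2)})

    def test_single_perfect_placement(self):
        genome = self._genome()
        conv = build_converted_reference(genome)
        m = placement(1000, "AT" * 50, "a", WATSON, ref_start=0, unique=True)
        stats = coverage_stats([m], genome, conv)
        assert stats.covered_fraction == pytest.approx(0.1)
        assert stats.mean_depth == pytest.approx(1.0)
        assert stats.consistency_pct == pytest.approx(100.0)

    def test_two_adjacent_placements(self):
        genome = self._genome()
        conv = build_converted_reference(genome)
        ms = [
            placement(1000, "AT" * 25, "a", WATSON, ref_start=0, unique=True),
            placement(1000, "AT" * 25, "a", WATSON, ref_start=50, unique=True,
                      read_id="r2"),
        ]
        stats = coverage_stats(ms, genome, conv)
        assert stats.covered_fraction == pytest.approx(0.1)
        assert stats.mean_depth == pytest.approx(1.0)

    def test_mismatches_reduce_consistency(self):
        genome = self._genome()
        conv = build_converted_reference(genome)
        bases = list("AT" * 50)
        bases[10] = bases[20] = "G"  # 2 mismatching bases out of 100
        m = placement(1000, "".join(bases), "a", WATSON, ref_start=0, unique=True)
        stats = coverage_stats([m], genome, conv)
        assert stats.consistency_pct == pytest.approx(98.0)

    def test_non_unique_placements_ignored(self):
        genome = self._genome()
        conv = build_converted_reference(genome)
        m = placement(1000, "AT" * 50, "a", WATSON, ref_start=0, unique=False)
        stats = coverage_stats([m], genome, conv)
        assert stats.covered_positions == 0
        assert math.isnan(stats.mean_depth)

    def test_conversion_blind_consistency(self):
        # a fully converted read still matches the converted reference
        genome = ReferenceGenome({"c": "ACGACG" * 20})
        conv = build_converted_reference(genome)
        m = placement(120, "ATGATG" * 20, "a", WATSON, ref_start=0, unique=True)
        assert coverage_stats([m], genome, conv).consistency_pct == 100.0
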