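import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ffpemeth import (
    SimulationConfig,
    assign_methylome,
    generate_reads,
    score_against_truth,
    simulate_genome,
)
from ffpemeth.bisulfite import WATSON
from ffpemeth.methylation import CPG, site_context
from ffpemeth.simulate import truncnorm_mean

SMALL = SimulationConfig(
    genome_length=20_000, n_reads=300, length_mean=120, length_sd=40,
    length_max=400, seed=7,
)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        g1, r1 = simulate_genome(SMALL)
        g2, r2 = simulate_genome(SMALL)
        assert g1.sequences == g2.sequences and r1 == r2

    def test_different_seeds_differ(self):
        g1, _ = simulate_genome(SMALL)
        g2, _ = simulate_genome(replace(SMALL, seed=8))
        assert g1.sequences != g2.sequences

    def test_gc_zero_gives_at_only(self):
        cfg = replace(SMALL, gc_fraction=0.0, repeat_fraction=0.0)
        genome, _ = simulate_genome(cfg)
        assert set(genome["sim1"]) <= {"A", "T"}

    def test_repeat_fraction_bound(self):
        cfg = replace(SMALL, genome_length=50_000, repeat_fraction=0.10)
        _, repeats = simulate_genome(cfg)
        total = sum(iv.end - iv.start for iv in repeats)
        assert 0.08 <= total / cfg.genome_length <= 0.12

    def test_repeat_classes_are_recognized_labels(self):
        _, repeats = simulate_genome(SMALL)
        assert {iv.repeat_class for iv in repeats} <= set(SMALL.repeat_classes)

    def test_too_small_genome_is_error(self):
        with pytest.raises(ValueError, match="1 kb"):
            simulate_genome(replace(SMALL, genome_length=500))

    def test_cpg_enrichment_raises_density(self):
        base, _ = simulate_genome(replace(SMALL, repeat_fraction=0.0))
        rich, _ = simulate_genome(
            replace(SMALL, repeat_fraction=0.0, cpg_enrichment=3.0)
        )
        assert rich["sim1"].count("CG") > 1.5 * base["sim1"].count("CG")


class TestAssignMethylome:
    def test_probability_one_methylates_every_watson_cpg(self):
        cfg = replace(SMALL, meth_cpg_watson=1.0)
        genome, _ = simulate_genome(cfg)
        methylome = assign_methylome(genome, cfg)
        for (contig, strand, pos), state in methylome.items():
            if strand == WATSON and site_context(genome, contig, pos, WATSON) == CPG:
                assert state

    def test_all_zero_probabilities(self):
        cfg = replace(
            SMALL, meth_cpg_watson=0.0, meth_cpg_crick=0.0,
            meth_cpa_watson=0.0, meth_cpa_crick=0.0,
        )
        genome, _ = simulate_genome(cfg)
        assert not any(assign_methylome(genome, cfg).values())

    def test_binomial_recovery_of_site_probability(self):
        cfg = replace(SMALL, genome_length=50_000, meth_cpg_watson=0.65)
        genome, _ = simulate_genome(cfg)
        methylome = assign_methylome(genome, cfg)
        states = [
            s for (contig, strand, pos), s in methylome.items()
            if strand == WATSON and site_context(genome, contig, pos, WATSON) == CPG
        ]
        assert len(states) >= 500
        p_hat = sum(states) / len(states)
        se = math.sqrt(0.65 * 0.35 / len(states))
        assert abs(p_hat - 0.65) <= 3 * se


class TestGenerateReads:
    def test_full_determinism(self):
        genome, _ = simulate_genome(SMALL)
        methylome = assign_methylome(genome, SMALL)
        r1, t1 = generate_reads(genome, methylome, SMALL)
        r2, t2 = generate_reads(genome, methylome, SMALL)
        assert r1 == r2 and t1 == t2

    def test_complete_conversion_leaves_no_c(self):
        cfg = replace(
            SMALL, conversion=1.0, error_rate=0.0, chimera_fraction=0.0,
            meth_cpg_watson=0.0, meth_cpg_crick=0.0, meth_cpa_watson=0.0,
            meth_cpa_crick=0.0, strand_mixture=(1.0, 0.0, 0.0, 0.0),
        )
        genome, _ = simulate_genome(cfg)
        reads, _ = generate_reads(genome, assign_methylome(genome, cfg), cfg)
        assert all("C" not in r.bases for r in reads)

    def test_zero_conversion_reproduces_genome(self):
        cfg = replace(
            SMALL, conversion=0.0, error_rate=0.0, chimera_fraction=0.0,
            strand_mixture=(1.0, 0.0, 0.0, 0.0),
        )
        genome, _ = simulate_genome(cfg)
        reads, truths = generate_reads(genome, assign_methylome(genome, cfg), cfg)
        for read, truth in zip(reads, truths):
            contig, start, end, state = truth.segments[0]
            assert read.bases == genome[contig][start:end]

    def test_length_distribution_matches_truncated_normal(self):
        cfg = replace(SMALL, n_reads=5_000, chimera_fraction=0.0)
        genome, _ = simulate_genome(cfg)
        reads, _ = generate_reads(genome, assign_methylome(genome, cfg), cfg)
        lengths = np.array([len(r) for r in reads], dtype=float)
        a = (cfg.length_min - cfg.length_mean) / cfg.length_sd
        b = (cfg.length_max - cfg.length_mean) / cfg.length_sd
        expected = truncnorm_mean(cfg)
        sd = stats.truncnorm.std(a, b, loc=cfg.length_mean, scale=cfg.length_sd)
        assert abs(lengths.mean() - expected) <= 3 * sd / math.sqrt(len(lengths))
        assert lengths.min() >= cfg.length_min and lengths.max() <= cfg.length_max

    def test_bisulfite_base_depletion_asymmetry(self):
        genome, _ = simulate_genome(replace(SMALL, repeat_fraction=0.0))
        methylome = assign_methylome(genome, SMALL)
        c_frac_genome = genome["sim1"].count("C") / len(genome["sim1"])
        g_frac_genome = genome["sim1"].count("G") / len(genome["sim1"])

        def base_fraction(mixture, base):
            cfg = replace(SMALL, strand_mixture=mixture, chimera_fraction=0.0)
            reads, _ = generate_reads(genome, methylome, cfg)
            total = sum(len(r) for r in reads)
            return sum(r.bases.count(base) for r in reads) / total

        # direct-template reads ('a'-phase) are C-depleted, complement
        # reads ('b'-phase) G-depleted, relative to the genome
        assert base_fraction((1.0, 0.0, 0.0, 0.0), "C") < 0.6 * c_frac_genome
        assert base_fraction((0.0, 0.0, 1.0, 0.0), "G") < 0.6 * g_frac_genome

    def test_zero_reads_is_error(self):
        genome, _ = simulate_genome(SMALL)
        with pytest.raises(ValueError, match="read count"):
            generate_reads(genome, {}, replace(SMALL, n_reads=0))

    def test_chimera_fraction_produces_two_segment_truths(self):
        cfg = replace(SMALL, chimera_fraction=1.0, length_mean=200)
        genome, _ = simulate_genome(cfg)
        _, truths = generate_reads(genome, assign_methylome(genome, cfg), cfg)
        assert any(t.chimeric for t in truths)
        for t in truths:
            if t.chimeric:
                assert len(t.segments) == 2


class TestScoreAgainstTruth:
    def test_shuffled_truth_ids_raise(self):
        genome, _ = simulate_genome(SMALL)
        methylome = assign_methylome(genome, SMALL)
        reads, truths = generate_reads(genome, methylome, SMALL)
        from ffpemeth.align import MappingResult

        bogus = MappingResult(
            read_id="not-a-read", query_id="not-a-read", tag="a",
            contig="sim1", strand=WATSON, ref_start=0, ref_end=50,
            read_start=0, read_end=50, score=50, cigar="50M",
            read_bases="A" * 50, contig_length=SMALL.genome_length,
        )
        with pytest.raises(ValueError, match="not in truth"):
            score_against_truth([bogus], truths)

    def test_expected_fraction_boundaries(self):
        from ffpemeth.simulate import expected_observed_fraction

        assert expected_observed_fraction(True, 0.9, 0.0) == 1.0
        assert expected_observed_fraction(False, 1.0, 0.0) == 0.0
        # conversion failure makes an unmethylated site look methylated
        assert expected_observed_fraction(False, 0.9, 0.0) == pytest.approx(0.1)
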