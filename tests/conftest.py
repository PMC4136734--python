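import random

import pytest
from hypothesis import settings

from ffpemeth import AlignmentParams, RawRead, ReferenceGenome, RepeatPolicy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params() -> AlignmentParams:
    return AlignmentParams()


@pytest.fixture
def policy() -> RepeatPolicy:
    return RepeatPolicy()


def random_sequence(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def small_genome() -> ReferenceGenome:
    rng = random.Random(1234)
    return ReferenceGenome({"chr1": random_sequence(rng, 5_000)})


def make_read(read_id: str, bases: str) -> RawRead:
    return RawRead(read_id, bases)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A small simulated dataset (genome, repeats, reads) written to disk."""
    from ffpemeth import (
        SimulationConfig,
        assign_methylome,
        generate_reads,
        simulate_genome,
        write_fasta,
        write_fastq,
        write_repeat_bed,
    )

    config = SimulationConfig(
        genome_length=12_000, n_reads=150, length_mean=120, length_sd=40,
        length_max=400, repeat_fraction=0.08, seed=21,
    )
    genome, repeats = simulate_genome(config)
    methylome = assign_methylome(genome, config)
    reads, truths = generate_reads(genome, methylome, config)
    root = tmp_path_factory.mktemp("sim_dataset")
    write_fasta(genome.sequences, root / "genome.fa")
    write_repeat_bed(repeats, root / "repeats.bed")
    write_fastq(reads, root / "reads.fastq")
    return {
        "root": root,
        "config": config,
        "genome": genome,
        "repeats": repeats,
        "methylome": methylome,
        "reads": reads,
        "truths": truths,
        "genome_fa": root / "genome.fa",
        "repeats_bed": root / "repeats.bed",
        "reads_fastq": root / "reads.fastq",
    }
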