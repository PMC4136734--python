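"""Read-length summaries and length-binned mapping-ratio profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import RawRead, fmt_na, fmt_pct


@dataclass
class ReadLengthSummary:
    """Table-1-style read length statistics.

    ``raw_wells`` / ``key_pass_wells`` are instrument-level counts upstream
    of the pipeline; they cannot be computed from read files and render as
    NA unless provided via configuration.
    """

    count: int
    total_bases: int
    mean_length: float
    std_length: float
    longest: int | None
    shortest: int | None
    median_length: float
    raw_wells: int | None = None
    key_pass_wells: int | None = None

    def as_table_column(self) -> dict[str, str]:
        return {
            "Raw wells": fmt_na(self.raw_wells, ","),
            "Key pass wells": fmt_na(self.key_pass_wells, ","),
            "Passed filter wells": format(self.count, ","),
            "Total bases": format(self.total_bases, ","),
            "Length average": fmt_na(self.mean_length, ".2f"),
            "Length std deviation": fmt_na(self.std_length, ".2f"),
            "Longest read length": fmt_na(self.longest),
            "Shortest read length": fmt_na(self.shortest),
            "Median read length": fmt_na(self.median_length, "g"),
        }


def summarize_lengths(
    reads: Sequence[RawRead] | Sequence[int],
    ddof: int = 0,
    raw_wells: int | None = None,
    key_pass_wells: int | None = None,
) -> ReadLengthSummary:
    """Length statistics over reads (or plain lengths).

    The standard deviation is the population form by default (``ddof=0``);
    pass ``ddof=1`` for the sample form.  An even count's median is the
    mean of the two central values.  An empty input yields a zero-count
    summary with NA statistics.
    """
    lengths = np.asarray(
        [len(r) if isinstance(r, RawRead) else int(r) for r in reads],
        dtype=np.int64,
    )
    if lengths.size == 0:
        return ReadLengthSummary(
            0, 0, math.nan, math.nan, None, None, math.nan,
            raw_wells, key_pass_wells,
        )
    return ReadLengthSummary(
        count=int(lengths.size),
        total_bases=int(lengths.sum()),
        mean_length=float(lengths.mean()),
        std_length=float(lengths.std(ddof=ddof)) if lengths.size > ddof else math.nan,
        longest=int(lengths.max()),
        shortest=int(lengths.min()),
        median_length=float(np.median(lengths)),
        raw_wells=raw_wells,
        key_pass_wells=key_pass_wells,
    )


@dataclass
class ReadFate:
    """Final per-read classification used for conservation accounting."""

    read_id: str
    fate: str  # unique | multi | filtered | unmapped
    reason: str | None = None
    mapped: bool = False  # had >= 1 candidate placement (step 1 or remap)


FATES = ("unique", "multi", "filtered", "unmapped")


@dataclass
class AlignmentSummary:
    """Table-2-style alignment statistics."""

    total_reads: int
    reads_mapped: int
    reads_unique: int
    total_length_all: int
    total_length_unique: int
    aligned_bases_unique: int
    consistency_pct: float
    covered_fraction: float
    mean_depth: float

    @property
    def mapped_pct(self) -> float:
        return 100.0 * self.reads_mapped / self.total_reads if self.total_reads else math.nan

    @property
    def unique_pct(self) -> float:
        return 100.0 * self.reads_unique / self.total_reads if self.total_reads else math.nan

    def as_table_column(self) -> dict[str, str]:
        len_ratio = (
            100.0 * self.total_length_unique / self.total_length_all
            if self.total_length_all else math.nan
        )
        base_ratio = (
            100.0 * self.aligned_bases_unique / self.total_length_all
            if self.total_length_all else math.nan
        )
        return {
            "Total number of reads": format(self.total_reads, ","),
            "Total number of reads mapped": format(self.reads_mapped, ","),
            "Total number of reads mapped/Total number of reads": fmt_pct(self.mapped_pct),
            "Total number of reads uniquely mapped": format(self.reads_unique, ","),
            "Total number of reads uniquely mapped/Total number of reads": fmt_pct(self.unique_pct),
            "Total length (bp) of all reads": format(self.total_length_all, ","),
            "Total length (bp) of unique mapped reads": format(self.total_length_unique, ","),
            "Total length of unique mapped reads/Total length of all reads": fmt_pct(len_ratio),
            "Total bases of unique mapped reads": format(self.aligned_bases_unique, ","),
            "Total bases of unique mapped reads/Total bases of all reads": fmt_pct(base_ratio),
            "Consistency rate": fmt_pct(self.consistency_pct),
            "Total number of bases covered in the genome": fmt_na(
                self.covered_fraction, ".3g"
            ),
            "Depth (x-fold)": fmt_na(self.mean_depth, ".2f"),
        }


def build_alignment_summary(
    reads: Sequence[RawRead],
    fates: Mapping[str, ReadFate],
    placements,
    coverage,
) -> AlignmentSummary:
    unique_ids = {f.read_id for f in fates.values() if f.fate == "unique"}
    lengths = {r.id: len(r) for r in reads}
    aligned_unique = sum(m.aligned_length for m in placements if m.unique)
    return AlignmentSummary(
        total_reads=len(reads),
        reads_mapped=sum(1 for f in fates.values() if f.mapped),
        reads_unique=len(unique_ids),
        total_length_all=sum(lengths.values()),
        total_length_unique=sum(lengths[i] for i in unique_ids),
        aligned_bases_unique=aligned_unique,
        consistency_pct=coverage.consistency_pct,
        covered_fraction=coverage.covered_fraction,
        mean_depth=coverage.mean_depth,
    )


@dataclass
class LengthBinProfile:
    """Per-length-bin all/mapped/unique counts with derived ratios."""

    edges: np.ndarray  # bin edges, len = nbins + 1
    all_counts: np.ndarray
    mapped_counts: np.ndarray
    unique_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            mapped_ratio = np.where(
                self.all_counts > 0, self.mapped_counts / self.all_counts, np.nan
            )
            unique_ratio = np.where(
                self.mapped_counts > 0,
                self.unique_counts / self.mapped_counts,
                np.nan,
            )
        return pd.DataFrame(
            {
                "bin_start": self.edges[:-1].astype(int),
                "bin_end": self.edges[1:].astype(int),
                "all_reads": self.all_counts.astype(int),
                "mapped_reads": self.mapped_counts.astype(int),
                "unique_reads": self.unique_counts.astype(int),
                "mapped_to_all": [fmt_na(v, ".4f") for v in mapped_ratio],
                "unique_to_mapped": [fmt_na(v, ".4f") for v in unique_ratio],
            }
        )


def bin_profile(
    reads: Sequence[RawRead],
    fates: Mapping[str, ReadFate],
    bin_width: int = 40,
    start: int = 40,
) -> LengthBinProfile:
    """Histogram read counts by length for all / mapped / unique reads.

    Fixed-width bins from ``start`` to the maximum read length; lengths
    outside the range are clipped into the edge bins so no read is lost.
    """
    lengths = np.asarray([len(r) for r in reads], dtype=np.int64)
    if lengths.size == 0:
        edges = np.asarray([start, start + bin_width])
        zeros = np.zeros(1, dtype=np.int64)
        return LengthBinProfile(edges, zeros.copy(), zeros.copy(), zeros.copy())
    top = max(int(lengths.max()), start + 1)
    nbins = -(-(top - start) // bin_width)  # ceil
    edges = start + bin_width * np.arange(nbins + 1)
    idx = np.clip((lengths - start) // bin_width, 0, nbins - 1)
    all_counts = np.bincount(idx, minlength=nbins)
    mapped_mask = np.asarray([fates[r.id].mapped for r in reads])
    unique_mask = np.asarray([fates[r.id].fate == "unique" for r in reads])
    mapped_counts = np.bincount(idx[mapped_mask], minlength=nbins)
    unique_counts = np.bincount(idx[unique_mask], minlength=nbins)
    return LengthBinProfile(edges, all_counts, mapped_counts, unique_counts)


def plot_length_profile(profile: LengthBinProfile, path) -> None:
    """Optional plot of the binned counts (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (profile.edges[:-1] + profile.edges[1:]) / 2
    width = (profile.edges[1] - profile.edges[0]) * 0.9
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, profile.all_counts, width=width, label="all", alpha=0.5)
    ax.bar(centers, profile.mapped_counts, width=width, label="mapped", alpha=0.7)
    ax.bar(centers, profile.unique_counts, width=width, label="unique", alpha=0.9)
    ax.set_xlabel("read length (bp)")
    ax.set_ylabel("reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
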