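"""Read-to-count summarization.

Three counting rules are provided:

* sliding windows count *fragments* — reads directionally extended to the
  average fragment length — that overlap each window;
* peak intervals count 5' read ends falling inside the interval;
* large genomic bins partition the genome and count 5' ends, feeding the
  scaling normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    FORWARD,
    REVERSE,
    CountMatrix,
    GenomicInterval,
    Read,
    ReadLibrary,
    as_genome,
)


@dataclass(frozen=True)
class WindowGrid:
    """Equispaced windows ``[j*spacing, j*spacing + width)`` along a genome.

    Width is 1 bp for transcription-factor data (the narrowest feature) and
    150 bp for histone marks (one nucleosome); spacings of 25-100 bp trade
    resolution against work.  Because widths are equal across windows, the
    spacing between starts equals the spacing between midpoints.
    """

    width: int
    spacing: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.spacing < 1 or self.genome_length < 1:
            raise ValueError("width, spacing and genome_length must be >= 1")

    @property
    def n_windows(self) -> int:
        # every window whose start lies inside the genome
        return (self.genome_length - 1) // self.spacing + 1

    def interval(self, j: int, chrom: str = "chrSim") -> GenomicInterval:
        start = j * self.spacing
        return GenomicInterval(chrom, start, min(start + self.width, self.genome_length))


def extend_read(read: Read, f: int) -> GenomicInterval:
    """Directionally extend a read to fragment length ``f``.

    Forward reads cover ``[pos5, pos5 + f)``; reverse reads cover the ``f``
    bases ending at (and including) their 5' end, ``[pos5 - f + 1, pos5 + 1)``.
    """
    if f < 1:
        raise ValueError("fragment length must be >= 1")
    if read.strand == FORWARD:
        return GenomicInterval(read.chrom, read.pos5, read.pos5 + f)
    return GenomicInterval(read.chrom, max(read.pos5 - f + 1, 0), read.pos5 + 1)


def _fragment_bounds(lib: ReadLibrary, chrom: str, f: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised fragment [start, end) bounds for all reads on one chromosome."""
    mask = lib.chrom == chrom
    pos = lib.pos5[mask]
    strand = lib.strand[mask]
    start = np.where(strand == FORWARD, pos, np.maximum(pos - f + 1, 0))
    end = np.where(strand == FORWARD, pos + f, pos + 1)
    return start, end


def count_windows(
    libs: Sequence[ReadLibrary],
    grid: WindowGrid,
    f: int,
    chrom: str = "chrSim",
    keep_empty: bool = False,
) -> CountMatrix:
    """Count extended fragments overlapping each sliding window.

    A fragment ``[s, e)`` overlaps window ``[j*sp, j*sp + w)`` iff
    ``ceil((s - w + 1)/sp) <= j <= floor((e - 1)/sp)``; the count therefore
    includes reads lying immediately upstream of the window on their own
    strand.  Windows with zero counts in every library are dropped unless
    ``keep_empty`` is set.
    """
    nwin = grid.n_windows
    sp, w = grid.spacing, grid.width
    counts = np.zeros((nwin, len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        s, e = _fragment_bounds(lib, chrom, f)
        if len(s) == 0:
            continue
        j_lo = np.maximum(-(-(s - w + 1) // sp), 0)  # ceil division
        j_hi = np.minimum((e - 1) // sp, nwin - 1)
        valid = j_lo <= j_hi
        j_lo, j_hi = j_lo[valid], j_hi[valid]
        diff = np.zeros(nwin + 1, dtype=np.int64)
        np.add.at(diff, j_lo, 1)
        np.add.at(diff, j_hi + 1, -1)
        counts[:, j] = np.cumsum(diff[:-1])
    if not keep_empty:
        keep = counts.any(axis=1)
    else:
        keep = np.ones(nwin, dtype=bool)
    idx = np.flatnonzero(keep)
    features = [grid.interval(int(i), chrom) for i in idx]
    return CountMatrix(features, [l.label for l in libs], counts[idx])


def count_5prime(
    libs: Sequence[ReadLibrary], intervals: Sequence[GenomicInterval]
) -> CountMatrix:
    """Count 5' read ends lying in each interval, per library (strand ignored)."""
    if not intervals:
        raise ValueError("no intervals to count over")
    chroms = sorted({iv.chrom for iv in intervals})
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    ends = np.array([iv.end for iv in intervals], dtype=np.int64)
    counts = np.zeros((len(intervals), len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        for chrom in chroms:
            rows = np.flatnonzero(np.fromiter(
                (iv.chrom == chrom for iv in intervals), bool, len(intervals)
            ))
            pos = np.sort(lib.positions_on(chrom))
            if len(pos) == 0:
                continue
            counts[rows, j] = np.searchsorted(pos, ends[rows], "left") - np.searchsorted(
                pos, starts[rows], "left"
            )
    return CountMatrix(list(intervals), [l.label for l in libs], counts)


def count_bins(
    libs: Sequence[ReadLibrary],
    genome: int | Mapping[str, int],
    bin_size: int = 10_000,
) -> CountMatrix:
    """Count 5' ends into contiguous fixed-size bins tiling the genome.

    Bins partition each chromosome as ``[k*bin_size, (k+1)*bin_size)`` with a
    truncated final bin, so column totals equal library sizes for reads inside
    the genome.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    genome = as_genome(genome)
    features: list[GenomicInterval] = []
    blocks: list[np.ndarray] = []
    for chrom, length in genome.items():
        nbin = -(-length // bin_size)
        features.extend(
            GenomicInterval(chrom, k * bin_size, min((k + 1) * bin_size, length))
            for k in range(nbin)
        )
        per_lib = np.zeros((nbin, len(libs)), dtype=np.int64)
        for j, lib in enumerate(libs):
            pos = lib.positions_on(chrom)
            if len(pos) == 0:
                continue
            if pos.max() >= length:
                raise ValueError(f"read position beyond {chrom} length {length}")
            per_lib[:, j] = np.bincount(pos // bin_size, minlength=nbin)
        blocks.append(per_lib)
    counts = np.vstack(blocks) if blocks else np.zeros((0, len(libs)), dtype=np.int64)
    return CountMatrix(features, [l.label for l in libs], counts)


def filter_features(
    cm: CountMatrix,
    min_total: int = 20,
    min_avelogcpm: float | None = None,
    eff_sizes: np.ndarray | None = None,
) -> CountMatrix:
    """Drop low-abundance features ahead of differential testing.

    Features are kept when their total count across libraries is at least
    ``min_total`` and, when ``min_avelogcpm`` is given, their average log2
    count-per-million is at least that value.  The abundance filter is meant
    for real data; simulated analyses use only the total-count rule.
    """
    keep = cm.row_totals() >= min_total
    if min_avelogcpm is not None:
        from .dbtest import ave_log_cpm

        sizes = eff_sizes if eff_sizes is not None else cm.column_totals().astype(float)
        keep &= ave_log_cpm(cm, sizes) >= min_avelogcpm
    return cm.subset(keep)
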