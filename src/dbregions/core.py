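"""Genomic coordinate conventions, read/count containers and plain-text I/O.

All coordinates are 0-based, half-open: an interval ``[start, end)`` covers
``end - start`` bases and adjacency never counts as overlap.  Reads are point
events carrying only a chromosome, the 5' end position and a strand; the
physical read length is never modelled because every counting rule downstream
consumes either the 5' end itself or a fragment-length extension anchored at
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

FORWARD: int = 1
REVERSE: int = -1

_STRAND_TO_INT = {"+": FORWARD, "-": REVERSE}
_INT_TO_STRAND = {FORWARD: "+", REVERSE: "-"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end})"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Intervals on different chromosomes never overlap; neither do adjacent
    half-open intervals.
    """
    if a.chrom != b.chrom:
        return False
    return max(a.start, b.start) < min(a.end, b.end)


@dataclass(frozen=True)
class Read:
    """A stranded point event anchored at the 5' end of a sequenced read."""

    chrom: str
    pos5: int
    strand: int  # FORWARD (+1) or REVERSE (-1)

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        if self.pos5 < 0:
            raise ValueError(f"negative position: {self.pos5}")


class ReadLibrary:
    """A sequencing library stored column-wise for vectorised counting.

    Parameters
    ----------
    label
        Library name used in count matrices and design tables.
    chrom, pos5, strand
        Parallel arrays of chromosome name, 5' end position and strand
        (+1 forward / -1 reverse), one entry per read.
    """

    def __init__(
        self,
        label: str,
        chrom: Sequence[str] | np.ndarray,
        pos5: Sequence[int] | np.ndarray,
        strand: Sequence[int] | np.ndarray,
    ) -> None:
        self.label = label
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos5 = np.asarray(pos5, dtype=np.int64)
        self.strand = np.asarray(strand, dtype=np.int8)
        if not (len(self.chrom) == len(self.pos5) == len(self.strand)):
            raise ValueError("chrom/pos5/strand lengths differ")
        if self.pos5.size and self.pos5.min() < 0:
            raise ValueError("negative 5' positions")
        if self.strand.size and not np.isin(self.strand, (FORWARD, REVERSE)).all():
            raise ValueError("strand entries must be +1/-1")

    @property
    def size(self) -> int:
        return int(len(self.pos5))

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[Read]:
        for c, p, s in zip(self.chrom, self.pos5, self.strand):
            yield Read(str(c), int(p), int(s))

    @classmethod
    def from_reads(cls, label: str, reads: Iterable[Read]) -> "ReadLibrary":
        reads = list(reads)
        return cls(
            label,
            [r.chrom for r in reads],
            [r.pos5 for r in reads],
            [r.strand for r in reads],
        )

    @classmethod
    def concatenate(cls, label: str, libs: Sequence["ReadLibrary"]) -> "ReadLibrary":
        """Pool several libraries into one (read order preserved)."""
        if not libs:
            return cls(label, [], [], [])
        return cls(
            label,
            np.concatenate([l.chrom for l in libs]),
            np.concatenate([l.pos5 for l in libs]),
            np.concatenate([l.strand for l in libs]),
        )

    def positions_on(self, chrom: str, strand: int | None = None) -> np.ndarray:
        """5' positions of reads on one chromosome (optionally one strand)."""
        mask = self.chrom == chrom
        if strand is not None:
            mask &= self.strand == strand
        return self.pos5[mask]

    def chromosomes(self) -> list[str]:
        return sorted({str(c) for c in self.chrom})


class CountMatrix:
    """Integer counts for a set of genomic features across libraries."""

    def __init__(
        self,
        features: Sequence[GenomicInterval],
        libraries: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(features), len(libraries)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(features)} features x {len(libraries)} libraries"
            )
        if counts.size and counts.min() < 0:
            raise ValueError("negative counts")
        self.features = list(features)
        self.libraries = list(libraries)
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset(self, rows: np.ndarray) -> "CountMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return CountMatrix(
            [self.features[i] for i in rows], self.libraries, self.counts[rows]
        )

    def starts(self) -> np.ndarray:
        return np.array([f.start for f in self.features], dtype=np.int64)

    def ends(self) -> np.ndarray:
        return np.array([f.end for f in self.features], dtype=np.int64)


@dataclass
class ExperimentDesign:
    """Two-group design with per-library sizes and scaling factors.

    The effective library size of each library is the product of its raw
    size and its normalization factor; the differential test consumes only
    effective sizes.
    """

    group: list[str]
    lib_size: np.ndarray
    norm_factor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        if self.norm_factor is None:
            self.norm_factor = np.ones_like(self.lib_size)
        self.norm_factor = np.asarray(self.norm_factor, dtype=float)
        if len(self.group) != len(self.lib_size) or len(self.group) != len(
            self.norm_factor
        ):
            raise ValueError("design columns have unequal lengths")
        labels = sorted(set(self.group))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        if (self.norm_factor <= 0).any():
            raise ValueError("normalization factors must be positive")
        self.group_labels = labels

    @property
    def n_libraries(self) -> int:
        return len(self.group)

    def effective_sizes(self) -> np.ndarray:
        return self.lib_size * self.norm_factor

    def group_indicator(self) -> np.ndarray:
        """Boolean vector: True for libraries in the second group label."""
        return np.array([g == self.group_labels[1] for g in self.group])


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3(+) file into a list of intervals (0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path,
    scores: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
) -> None:
    """Write BED3, or BED6 when scores are given (score column = value as-is)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else f"region_{i + 1}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                    f"{scores[i]:.6g}\t.\n"
                )


def read_reads_tsv(path, label: str | None = None) -> ReadLibrary:
    """Read a (chrom, pos5, strand) TSV into a ReadLibrary.

    Strand must be '+' or '-'; anything else is a parse error.
    """
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns")
            if parts[2] not in _STRAND_TO_INT:
                raise ParseError(
                    f"line {lineno}: unknown strand symbol {parts[2]!r}"
                )
            try:
                p = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad position") from exc
            chroms.append(parts[0])
            pos.append(p)
            strands.append(_STRAND_TO_INT[parts[2]])
    if label is None:
        label = str(path)
    return ReadLibrary(label, chroms, pos, strands)


def write_reads_tsv(lib: ReadLibrary, path) -> None:
    with open(path, "w") as fh:
        for c, p, s in zip(lib.chrom, lib.pos5, lib.strand):
            fh.write(f"{c}\t{p}\t{_INT_TO_STRAND[int(s)]}\n")


def read_counts_tsv(path) -> CountMatrix:
    """Read a counts TSV (name, chrom, start, end, one column per library)."""
    df = pd.read_csv(path, sep="\t")
    required = ["name", "chrom", "start", "end"]
    if list(df.columns[:4]) != required:
        raise ParseError(f"expected leading columns {required}")
    features = [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    libs = list(df.columns[4:])
    return CountMatrix(features, libs, df[libs].to_numpy())


def write_counts_tsv(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "name": [f"f{i + 1}" for i in range(len(cm.features))],
            "chrom": [f.chrom for f in cm.features],
            "start": [f.start for f in cm.features],
            "end": [f.end for f in cm.features],
        }
    )
    for j, lib in enumerate(cm.libraries):
        df[lib] = cm.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_bam(path, label: str | None = None) -> ReadLibrary:
    """Extract 5' ends and strands from a coordinate-indexed BAM file.

    Requires pysam; mapped reads only, no mapping-quality filtering and no
    duplicate collapsing.
    """
    import pysam  # local import: optional dependency

    chroms: list[str] = []
    pos: list[int] = []
    strands: list[int] = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                chroms.append(aln.reference_name)
                pos.append(aln.reference_end - 1)
                strands.append(REVERSE)
            else:
                chroms.append(aln.reference_name)
                pos.append(aln.reference_start)
                strands.append(FORWARD)
    return ReadLibrary(label or str(path), chroms, pos, strands)


def as_genome(genome: int | Mapping[str, int], default_chrom: str = "chrSim") -> dict[str, int]:
    """Normalise a genome description to a ``{chrom: length}`` mapping.

    A bare integer means a single synthetic chromosome of that length.
    """
    if isinstance(genome, Mapping):
        return dict(genome)
    return {default_chrom: int(genome)}
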