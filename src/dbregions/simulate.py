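"""Synthetic two-group ChIP-seq experiments with known truth.

The generator places ``N`` binding sites at least 10 kbp apart on one
artificial chromosome.  Per library, each site receives a negative-binomial
number of fragments with site-specific dispersion drawn as the reciprocal of
a chi-squared variate with 20 degrees of freedom (mean 1/18).  Differential
sites are spiked in balanced pairs: ``N'`` sites get group means (x1, x2) and
another ``N'`` sites the swap, with ``x1 + x2 = 2*x0`` so that abundance and
differential status stay uncorrelated.  Read 5' positions follow a Beta(2,2)
law — strand-bimodal around the site centre for transcription factors,
diffuse and strand-independent for histone marks.  Optional background blocks
add non-specific enrichment with block-constant means shared across
libraries, so background is never differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    FORWARD,
    REVERSE,
    CountMatrix,
    ExperimentDesign,
    GenomicInterval,
    ReadLibrary,
)

CHROM = "chrSim"


@dataclass
class BackgroundConfig:
    """Non-specific enrichment: per-block NB counts, uniform placement."""

    block: int = 2000
    mu_low: float = 10.0
    mu_high: float = 50.0


@dataclass
class SimulationConfig:
    N: int
    N_db: int = 0
    x0: float = 20.0
    x1: float = 0.0
    x2: float = 0.0
    mode: str = "TF"  # or "histone"
    f: int = 100
    hist_width: int = 1000
    peak_spacing: int = 10_000
    n_reps: int = 2
    dispersion_df: float = 20.0
    background: BackgroundConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("TF", "histone"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.N_db > 0:
            if 2 * self.N_db > self.N:
                raise ValueError("2*N_db exceeds N")
            if not np.isclose(self.x1 + self.x2, 2 * self.x0):
                raise ValueError("DB means must satisfy x1 + x2 = 2*x0")
        if self.dispersion_df <= 2:
            raise ValueError("dispersion_df must exceed 2")

    @property
    def genome_length(self) -> int:
        return (self.N + 2) * self.peak_spacing

    @property
    def region_half_width(self) -> int:
        return self.f if self.mode == "TF" else self.hist_width // 2


@dataclass
class TruePeak:
    index: int
    centre: int
    mu: tuple[float, float]
    phi: float
    is_db: bool
    region: GenomicInterval


@dataclass
class TruthTable:
    peaks: list[TruePeak]
    genome_length: int
    db_regions: list[GenomicInterval] = field(default_factory=list)

    # cached arrays for fast overlap queries (single chromosome, sorted)
    def __post_init__(self) -> None:
        self._starts = np.array([p.region.start for p in self.peaks], dtype=np.int64)
        self._ends = np.array([p.region.end for p in self.peaks], dtype=np.int64)
        self._is_db = np.array([p.is_db for p in self.peaks], dtype=bool)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def is_db_flags(self) -> np.ndarray:
        return self._is_db.copy()

    def regions(self) -> list[GenomicInterval]:
        return [p.region for p in self.peaks]

    def overlapping_peaks(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Indices of true peaks overlapped by >=1 query interval.

        Relies on true-peak regions being sorted and non-overlapping.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        lo = np.searchsorted(self._ends, starts, "right")
        hi = np.searchsorted(self._starts, ends, "left")
        hit: set[int] = set()
        for a, b in zip(lo, hi):
            if b > a:
                hit.update(range(int(a), int(b)))
        return np.array(sorted(hit), dtype=np.int64)

    def queries_overlapping_db(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean per query interval: does it overlap any DB true-peak region?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        db_starts = self._starts[self._is_db]
        db_ends = self._ends[self._is_db]
        order = np.argsort(db_starts)
        db_starts, db_ends = db_starts[order], db_ends[order]
        lo = np.searchsorted(db_ends, starts, "right")
        hi = np.searchsorted(db_starts, ends, "left")
        return hi > lo


def sample_dispersion(df: float, rng: np.random.Generator, size=None) -> np.ndarray | float:
    """Draw NB dispersions as 1/X with X ~ chi-squared(df); mean 1/(df-2)."""
    if df <= 2:
        raise ValueError("df must exceed 2 for the dispersion mean to exist")
    return 1.0 / rng.chisquare(df, size=size)


def build_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    """Lay out true peaks and assign group means, dispersions and DB status.

    Centres sit on a regular grid ``c_i = (i+1)*peak_spacing`` so successive
    sites are exactly one spacing apart; the region of site ``i`` spans all
    positions its reads can reach: ``[c_i - h, c_i + h]`` inclusive, stored
    half-open as ``[c_i - h, c_i + h + 1)`` with ``h = f`` for TF data and
    ``h = hist_width/2`` for histone data.
    """
    N, ndb = config.N, config.N_db
    centres = (np.arange(N, dtype=np.int64) + 1) * config.peak_spacing
    phi = sample_dispersion(config.dispersion_df, rng, size=N)
    mu1 = np.full(N, config.x0, dtype=float)
    mu2 = np.full(N, config.x0, dtype=float)
    is_db = np.zeros(N, dtype=bool)
    if ndb > 0:
        chosen = rng.choice(N, size=2 * ndb, replace=False)
        up1, up2 = chosen[:ndb], chosen[ndb:]
        mu1[up1], mu2[up1] = config.x1, config.x2
        mu1[up2], mu2[up2] = config.x2, config.x1
        is_db[chosen] = True
    h = config.region_half_width
    peaks = [
        TruePeak(
            index=i,
            centre=int(centres[i]),
            mu=(float(mu1[i]), float(mu2[i])),
            phi=float(phi[i]),
            is_db=bool(is_db[i]),
            region=GenomicInterval(CHROM, int(centres[i]) - h, int(centres[i]) + h + 1),
        )
        for i in range(N)
    ]
    db_regions = [p.region for p in peaks if p.is_db]
    return TruthTable(peaks=peaks, genome_length=config.genome_length, db_regions=db_regions)


def simulate_counts(
    truth: TruthTable, design: ExperimentDesign, rng: np.random.Generator
) -> CountMatrix:
    """Draw per-peak fragment counts: NB(mu_ij, phi_i), independent across
    libraries, with the same dispersion for every library of a peak."""
    mu_by_group = np.array([[p.mu[0], p.mu[1]] for p in truth.peaks])
    phi = np.array([p.phi for p in truth.peaks])
    grp2 = design.group_indicator()
    counts = np.zeros((truth.n_peaks, design.n_libraries), dtype=np.int64)
    for j in range(design.n_libraries):
        mu = mu_by_group[:, 1] if grp2[j] else mu_by_group[:, 0]
        counts[:, j] = _nb_draw(mu, phi, rng)
    return CountMatrix(truth.regions(), [f"lib{j + 1}" for j in range(design.n_libraries)], counts)


def _nb_draw(mu: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised NB(mu, phi) with variance mu + phi*mu^2; mu=0 gives 0."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        r = 1.0 / phi[pos]
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _even_strand_split(n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Forward-read counts for an exactly even split; odd remainders are
    assigned to the forward strand with probability 1/2."""
    n = np.asarray(n, dtype=np.int64)
    extra = (n % 2 == 1) & (rng.random(n.shape) < 0.5)
    return n // 2 + extra


def place_reads(
    centres: np.ndarray,
    n_reads: np.ndarray,
    mode: str,
    rng: np.random.Generator,
    f: int = 100,
    hist_width: int = 1000,
    genome_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample 5' positions and strands for the reads of each peak.

    TF mode: reads split evenly between strands; a forward read sits at
    ``round(c - f*X)`` and a reverse read at ``round(c + f*X)`` with
    ``X ~ Beta(2, 2)``, reproducing strand bimodality around the centre.
    Histone mode: ``round(c + w*(X - 1/2))`` with the strand assigned
    uniformly, independent of position.  Returns (pos5, strand) arrays over
    all peaks concatenated in peak order (forward block then reverse block
    within each TF peak).
    """
    centres = np.asarray(centres, dtype=np.int64)
    n_reads = np.asarray(n_reads, dtype=np.int64)
    total = int(n_reads.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    if mode == "TF":
        n_fwd = _even_strand_split(n_reads, rng)
        n_rev = n_reads - n_fwd
        c_fwd = np.repeat(centres, n_fwd)
        c_rev = np.repeat(centres, n_rev)
        x_fwd = rng.beta(2.0, 2.0, size=len(c_fwd))
        x_rev = rng.beta(2.0, 2.0, size=len(c_rev))
        pos = np.concatenate(
            [np.rint(c_fwd - f * x_fwd), np.rint(c_rev + f * x_rev)]
        ).astype(np.int64)
        strand = np.concatenate(
            [np.full(len(c_fwd), FORWARD, np.int8), np.full(len(c_rev), REVERSE, np.int8)]
        )
        # restore per-peak grouping: forward reads of peak i, then reverse
        order = np.argsort(
            np.concatenate([np.repeat(np.arange(len(centres)), n_fwd),
                            np.repeat(np.arange(len(centres)), n_rev)]),
            kind="stable",
        )
        pos, strand = pos[order], strand[order]
    elif mode == "histone":
        c = np.repeat(centres, n_reads)
        x = rng.beta(2.0, 2.0, size=total)
        pos = np.rint(c + hist_width * (x - 0.5)).astype(np.int64)
        strand = np.where(rng.random(total) < 0.5, FORWARD, REVERSE).astype(np.int8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.clip(pos, 0, None if genome_length is None else genome_length - 1, out=pos)
    return pos, strand


def simulate_background(
    genome_length: int,
    block_cfg: BackgroundConfig,
    dispersion_df: float,
    rng: np.random.Generator,
    n_libraries: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate non-specific background reads for each library.

    The genome is tiled with contiguous blocks; block means are U(mu_low,
    mu_high) and block dispersions inverse-chi-squared, both drawn once and
    shared by all libraries so that background regions are never
    differential.  Within a block, reads are uniform and strands evenly
    split.  Returns one (pos5, strand) pair per library.
    """
    block = block_cfg.block
    n_blocks = genome_length // block
    mu = rng.uniform(block_cfg.mu_low, block_cfg.mu_high, size=n_blocks)
    phi = sample_dispersion(dispersion_df, rng, size=n_blocks)
    block_starts = np.arange(n_blocks, dtype=np.int64) * block
    out = []
    for _ in range(n_libraries):
        counts = _nb_draw(mu, phi, rng)
        starts = np.repeat(block_starts, counts)
        offsets = rng.integers(0, block, size=len(starts))
        pos = starts + offsets
        n_fwd = _even_strand_split(counts, rng)
        in_block_rank = np.arange(len(starts)) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
        )
        strand = np.where(in_block_rank < np.repeat(n_fwd, counts), FORWARD, REVERSE).astype(
            np.int8
        )
        out.append((pos, strand))
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[TruthTable, list[ReadLibrary], CountMatrix, ExperimentDesign]:
    """Run the full generator: truth, per-library reads and the true counts.

    Deterministic given ``config.seed``.  Library labels are
    ``g<j>_rep<k>``; the design's raw library sizes are the realised read
    totals (signal plus any background).
    """
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config, rng)
    n_lib = 2 * config.n_reps
    groups = ["g1"] * config.n_reps + ["g2"] * config.n_reps
    labels = [f"g{1 if j < config.n_reps else 2}_rep{j % config.n_reps + 1}" for j in range(n_lib)]
    design = ExperimentDesign(group=groups, lib_size=np.ones(n_lib))
    counts = simulate_counts(truth, design, rng)
    centres = np.array([p.centre for p in truth.peaks], dtype=np.int64)

    libs: list[ReadLibrary] = []
    for j in range(n_lib):
        pos, strand = place_reads(
            centres,
            counts.counts[:, j],
            config.mode,
            rng,
            f=config.f,
            hist_width=config.hist_width,
            genome_length=config.genome_length,
        )
        libs.append((pos, strand))

    if config.background is not None:
        bg = simulate_background(
            config.genome_length, config.background, config.dispersion_df, rng, n_lib
        )
        libs = [
            (np.concatenate([p, bp]), np.concatenate([s, bs]))
            for (p, s), (bp, bs) in zip(libs, bg)
        ]

    read_libs = [
        ReadLibrary(labels[j], np.full(len(p), CHROM, dtype=object), p, s)
        for j, (p, s) in enumerate(libs)
    ]
    counts = CountMatrix(counts.features, labels, counts.counts)
    design = ExperimentDesign(
        group=groups, lib_size=np.array([l.size for l in read_libs], dtype=float)
    )
    return truth, read_libs, counts, design
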