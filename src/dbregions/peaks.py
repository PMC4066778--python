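"""A simplified Poisson peak caller and the seven consolidation strategies.

The caller emulates the behaviour of a conventional single-sample ChIP-seq
peak caller run without model building: each read's 5' end is shifted by half
the fragment length towards the fragment midpoint, the genome is scanned in
fragment-width windows at quarter-width steps, each window count is scored
against a Poisson null whose rate is the larger of the genome-wide and the
local (10 kbp) shifted-read density, and overlapping or adjacent significant
windows are merged into peaks.  The two-sample variant derives the window
rate from a control library scaled by the library-size ratio.

For experiments with several libraries or groups, a peak set is called per
unit and *consolidated*: peaks are matched across units by single-linkage
interval overlap, a missing match contributes a peak-calling P-value of 1,
and each strategy reduces the per-unit P-values of a matched peak to one
consolidated value (minimum = union, maximum = intersection, second-smallest
= present in at least two).  The consolidation threshold is set so that a
fixed number of peaks ``C`` is retained, making strategies comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import FORWARD, GenomicInterval, ReadLibrary, as_genome

_SEED_PVALUE = 0.1  # window seed threshold for merging
_LOCAL_SPAN = 10_000  # bp over which the local background rate is estimated
_MACS_PVALUE = 1e-5  # conventional final peak P-value cutoff


@dataclass
class EmpiricalPeak:
    interval: GenomicInterval
    pvalue: float
    summit: int


@dataclass
class ConsolidatedPeakSet:
    strategy_id: int
    peaks: list[tuple[GenomicInterval, float]]
    tau: float
    C: int
    truth_intervals: list[GenomicInterval] | None = None

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.peaks]


def _shifted_positions(lib: ReadLibrary, chrom: str, f: int, length: int) -> np.ndarray:
    """5' positions shifted by f/2 towards the fragment midpoint, clamped."""
    mask = lib.chrom == chrom
    pos = lib.pos5[mask] + np.where(lib.strand[mask] == FORWARD, f // 2, -(f // 2))
    return np.clip(pos, 0, length - 1)


def _density_at(
    cs: np.ndarray,
    lo_bin: np.ndarray,
    hi_bin: np.ndarray,
    step: int,
    n_bins: int,
    spans: tuple[int, ...],
) -> np.ndarray:
    """Max read density (per bp) around bin ranges over several scales.

    Each span is a window of that many bases centred on the query range's
    midpoint (clamped at the chromosome ends); the maximum density across
    scales is returned, as in conventional local-lambda peak calling.  A
    span of 0 means the query range itself.
    """
    centre = (lo_bin + hi_bin) // 2
    rate = np.zeros(lo_bin.shape, dtype=float)
    for span in spans:
        if span == 0:
            lo, hi = lo_bin, hi_bin
        else:
            half = max(span // (2 * step), 1)
            lo = np.maximum(centre - half, 0)
            hi = np.minimum(centre + half, n_bins)
        count = cs[hi] - cs[lo]
        np.maximum(rate, count / np.maximum((hi - lo) * step, 1), out=rate)
    return rate


def _scan_chrom(
    treat_pos: np.ndarray,
    length: int,
    f: int,
    chrom: str,
    seed_pvalue: float,
    max_pvalue: float | None,
    local_pos: np.ndarray,
    local_scale: float,
    floor_rate: float,
    window_spans: tuple[int, ...],
    region_spans: tuple[int, ...],
) -> list[EmpiricalPeak]:
    """Poisson window scan shared by the single- and two-sample callers.

    Windows of width ``f`` at quarter-width steps whose counts beat the local
    rate at the seed P-value are merged (overlapping or adjacent) into
    candidate peaks; each peak is then re-scored as a whole — its total
    shifted-read count against the local rate scaled to the peak width — so
    the reported P-value reflects the region, not the noisiest window.  The
    local rate comes from ``local_pos`` (the library itself for single-sample
    calling, the control for two-sample) as the maximum density across the
    given spans, times ``local_scale``, floored at ``floor_rate`` per base.
    """
    step = max(f // 4, 1)
    w_bins = max(f // step, 1)
    n_bins = -(-length // step)
    n_windows = max(n_bins - w_bins + 1, 1)
    binned = np.bincount(treat_pos // step, minlength=n_bins)
    cs = np.concatenate([[0], np.cumsum(binned)])
    wc = cs[w_bins : w_bins + n_windows] - cs[:n_windows]

    if np.shares_memory(local_pos, treat_pos) or local_pos is treat_pos:
        cs_local = cs
    else:
        cs_local = np.concatenate(
            [[0], np.cumsum(np.bincount(local_pos // step, minlength=n_bins))]
        )

    nz = np.flatnonzero(wc > 0)
    if nz.size == 0:
        return []
    dens = _density_at(
        cs_local, nz, np.minimum(nz + w_bins, n_bins), step, n_bins, window_spans
    )
    lam = np.maximum(dens * local_scale, floor_rate) * f
    pv = stats.poisson.sf(wc[nz] - 1, lam)

    seeds = pv <= seed_pvalue
    if not seeds.any():
        return []
    idx = nz[seeds]
    pv = pv[seeds]
    # merge windows that overlap or are adjacent: starts within w_bins steps
    breaks = np.flatnonzero(np.diff(idx) > w_bins)
    run_a = np.concatenate([[0], breaks + 1])
    run_b = np.concatenate([breaks, [idx.size - 1]])

    lo_bin = idx[run_a]
    hi_bin = np.minimum(idx[run_b] + w_bins, n_bins)
    region_count = cs[hi_bin] - cs[lo_bin]
    dens_r = _density_at(cs_local, lo_bin, hi_bin, step, n_bins, region_spans)
    width_bp = np.minimum(hi_bin * step, length) - lo_bin * step
    lam_r = np.maximum(dens_r * local_scale, floor_rate) * width_bp
    pv_r = np.maximum(stats.poisson.sf(region_count - 1, lam_r), 1e-300)

    out: list[EmpiricalPeak] = []
    for k, (a, b) in enumerate(zip(run_a, run_b)):
        p = float(pv_r[k])
        if max_pvalue is not None and p > max_pvalue:
            continue
        best = a + int(np.argmin(pv[a : b + 1]))
        lo = int(lo_bin[k]) * step
        hi = min(int(hi_bin[k]) * step, length)
        out.append(
            EmpiricalPeak(
                interval=GenomicInterval(chrom, lo, hi),
                pvalue=p,
                summit=int(idx[best]) * step + f // 2,
            )
        )
    return out


def call_peaks_single(
    lib: ReadLibrary,
    f: int,
    genome: int | Mapping[str, int],
    seed_pvalue: float = _SEED_PVALUE,
    max_pvalue: float | None = _MACS_PVALUE,
) -> list[EmpiricalPeak]:
    """Single-sample Poisson peak calling on one library.

    The rate is the larger of the genome-wide and the local 10 kbp
    shifted-read density, scaled to the window (or merged-peak) width.
    """
    genome = as_genome(genome)
    total_len = sum(genome.values())
    if lib.size == 0:
        return []
    rate_genome = lib.size / total_len
    out: list[EmpiricalPeak] = []
    for chrom, length in genome.items():
        pos = _shifted_positions(lib, chrom, f, length)
        if len(pos) == 0:
            continue
        out.extend(
            _scan_chrom(
                pos,
                length,
                f,
                chrom=chrom,
                seed_pvalue=seed_pvalue,
                max_pvalue=max_pvalue,
                local_pos=pos,
                local_scale=1.0,
                floor_rate=rate_genome,
                window_spans=(_LOCAL_SPAN,),
                region_spans=(_LOCAL_SPAN,),
            )
        )
    return out


def call_peaks_twosample(
    treatment: ReadLibrary,
    control: ReadLibrary,
    f: int,
    genome: int | Mapping[str, int],
    seed_pvalue: float = _SEED_PVALUE,
    max_pvalue: float | None = _MACS_PVALUE,
) -> list[EmpiricalPeak]:
    """Two-sample Poisson calling: enrichment of treatment over control.

    The rate derives from the control's shifted-read density — the maximum
    over the query range itself and 1 kbp and 10 kbp neighbourhoods, so a
    control peak at the same locus raises the bar and significance reflects
    the treatment/control contrast rather than sheer treatment abundance —
    scaled by the library-size ratio and floored at the control's
    genome-wide rate (zero-control windows never get a zero rate).
    """
    genome = as_genome(genome)
    total_len = sum(genome.values())
    if treatment.size == 0 or control.size == 0:
        return []
    ratio = treatment.size / control.size
    floor_rate = control.size / total_len * ratio
    out: list[EmpiricalPeak] = []
    for chrom, length in genome.items():
        tpos = _shifted_positions(treatment, chrom, f, length)
        cpos = _shifted_positions(control, chrom, f, length)
        if len(tpos) == 0:
            continue
        out.extend(
            _scan_chrom(
                tpos,
                length,
                f,
                chrom=chrom,
                seed_pvalue=seed_pvalue,
                max_pvalue=max_pvalue,
                local_pos=cpos,
                local_scale=ratio,
                floor_rate=floor_rate,
                window_spans=(0, 1_000, _LOCAL_SPAN),
                region_spans=(0, 1_000, _LOCAL_SPAN),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Consolidation strategies 1-7
# ---------------------------------------------------------------------------


def _overlap_clusters(
    peak_lists: Sequence[Sequence[EmpiricalPeak]],
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Single-linkage overlap clustering of peaks pooled across units.

    Returns the cluster span intervals and, per cluster x unit, the smallest
    member P-value (1 where the unit called no overlapping peak).
    """
    n_units = len(peak_lists)
    recs = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.pvalue, u)
        for u, plist in enumerate(peak_lists)
        for p in plist
    ]
    if not recs:
        return [], np.empty((0, n_units))
    recs.sort(key=lambda r: (r[0], r[1]))
    chroms = [r[0] for r in recs]
    starts = np.array([r[1] for r in recs], dtype=np.int64)
    ends = np.array([r[2] for r in recs], dtype=np.int64)
    pvals = np.array([r[3] for r in recs])
    units = np.array([r[4] for r in recs], dtype=np.int64)

    cluster_id = np.zeros(len(recs), dtype=np.int64)
    cid = 0
    run_end = ends[0]
    for i in range(1, len(recs)):
        if chroms[i] == chroms[i - 1] and starts[i] < run_end:
            run_end = max(run_end, ends[i])
        else:
            cid += 1
            run_end = ends[i]
        cluster_id[i] = cid
    n_clusters = cid + 1

    pmat = np.ones((n_clusters, n_units))
    np.minimum.at(pmat, (cluster_id, units), pvals)
    span_start = np.full(n_clusters, np.iinfo(np.int64).max, dtype=np.int64)
    span_end = np.zeros(n_clusters, dtype=np.int64)
    np.minimum.at(span_start, cluster_id, starts)
    np.maximum.at(span_end, cluster_id, ends)
    chrom_of = {}
    for i, c in enumerate(cluster_id):
        chrom_of.setdefault(int(c), chroms[i])
    intervals = [
        GenomicInterval(chrom_of[c], int(span_start[c]), int(span_end[c]))
        for c in range(n_clusters)
    ]
    return intervals, pmat


def _consolidated_values(strategy_id: int, pmat: np.ndarray) -> np.ndarray:
    if strategy_id in (1, 4):  # union: minimum
        return pmat.min(axis=1)
    if strategy_id in (2, 5):  # intersection: maximum
        return pmat.max(axis=1)
    if strategy_id == 3:  # present in at least two: second-smallest
        return np.sort(pmat, axis=1)[:, 1]
    raise ValueError(f"strategy {strategy_id} does not consolidate a P matrix")


def consolidate(
    strategy_id: int,
    per_unit_peaks: Sequence[Sequence[EmpiricalPeak]],
    C: int,
    truth_intervals: Sequence[GenomicInterval] | None = None,
) -> ConsolidatedPeakSet:
    """Reduce per-unit peak calls to at most ``C`` consolidated peaks.

    ``per_unit_peaks`` holds one list per library (strategies 1-3), per
    group-pooled library (4-5), the two directional two-sample lists (6), or
    the single all-pooled list (7).  The threshold tau is the C-th smallest
    consolidated P-value; all peaks are retained when fewer than C are
    available.  With ``truth_intervals`` (sorted, non-overlapping), every
    retained peak is re-mapped to the overlapping truth intervals, which are
    stored de-duplicated for downstream counting.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if strategy_id not in range(1, 8):
        raise ValueError(f"unknown strategy {strategy_id}")

    if strategy_id == 7:
        if len(per_unit_peaks) != 1:
            raise ValueError("strategy 7 takes a single pooled peak list")
        cand = [(p.interval, p.pvalue) for p in per_unit_peaks[0]]
    elif strategy_id == 6:
        if len(per_unit_peaks) != 2:
            raise ValueError("strategy 6 takes the two directional peak lists")
        intervals, pmat = _overlap_clusters(per_unit_peaks)
        # union over directions: overlapping calls keep the smaller P-value
        cand = list(zip(intervals, pmat.min(axis=1)))
    else:
        intervals, pmat = _overlap_clusters(per_unit_peaks)
        cand = list(zip(intervals, _consolidated_values(strategy_id, pmat)))

    cand.sort(key=lambda t: (t[1], t[0].start))
    kept = cand[:C]
    tau = kept[-1][1] if kept else 1.0

    truth_hits: list[GenomicInterval] | None = None
    if truth_intervals is not None and kept:
        t_starts = np.array([t.start for t in truth_intervals], dtype=np.int64)
        t_ends = np.array([t.end for t in truth_intervals], dtype=np.int64)
        k_starts = np.array([iv.start for iv, _ in kept], dtype=np.int64)
        k_ends = np.array([iv.end for iv, _ in kept], dtype=np.int64)
        lo = np.searchsorted(t_ends, k_starts, "right")
        hi = np.searchsorted(t_starts, k_ends, "left")
        hit: set[int] = set()
        for a, b in zip(lo, hi):
            hit.update(range(int(a), int(b)))
        truth_hits = [truth_intervals[i] for i in sorted(hit)]
    elif truth_intervals is not None:
        truth_hits = []

    return ConsolidatedPeakSet(
        strategy_id=strategy_id,
        peaks=kept,
        tau=float(tau),
        C=C,
        truth_intervals=truth_hits,
    )
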