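"""Region-level inference from window-level tests.

Controlling the FDR across windows does not control it across the genomic
regions those windows tile: a strong differential region contributes many
detected windows while a false region contributes few, so the region-level
false discovery proportion exceeds the window-level one.  The hybrid
procedure here restores region-level control by combining the P-values of all
windows in a peak cluster with Simes' method and applying Benjamini-Hochberg
across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GenomicInterval
from .dbtest import TestResult
from .simulate import TruthTable


@dataclass
class RegionResult:
    region: GenomicInterval
    member_windows: list[int]
    combined_p: float
    qvalue: float = np.nan
    direction: int = 0  # sign of the logFC of the most significant member


def simes(pvalues: Sequence[float] | np.ndarray) -> float:
    """Simes' combined P-value: ``min over r of n * p_(r) / r``, capped at 1.

    Tests the global null that no member hypothesis is false; gives weak
    family-wise control and is robust to the positive correlations typical of
    overlapping windows.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("simes requires at least one P-value")
    p = np.sort(p)
    n = p.size
    return float(min(1.0, (n * p / np.arange(1, n + 1)).min()))


def simes_grouped(pvalues: np.ndarray, group_ids: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorised Simes combination over many groups at once.

    ``group_ids`` assigns each P-value to a group in ``[0, n_groups)``;
    groups with no members get NaN.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    group_ids = np.asarray(group_ids)
    order = np.lexsort((pvalues, group_ids))
    g = group_ids[order]
    p = pvalues[order]
    counts = np.bincount(g, minlength=n_groups)
    first = np.concatenate([[0], np.cumsum(counts)[:-1]])
    rank = np.arange(len(p)) - np.repeat(first, counts) + 1
    stat = np.repeat(counts, counts) * p / rank
    out = np.full(n_groups, np.inf)
    np.minimum.at(out, g, stat)
    out = np.minimum(out, 1.0)
    out[counts == 0] = np.nan
    return out


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _cluster_sorted(starts: np.ndarray, ends: np.ndarray, max_gap: int) -> np.ndarray:
    """Single-linkage cluster ids for intervals sorted by start.

    Intervals join a cluster while ``start - running_end < max_gap`` (gap 0
    merges overlapping or bookended intervals when ``max_gap > 0``).
    """
    n = len(starts)
    ids = np.zeros(n, dtype=np.int64)
    if n == 0:
        return ids
    current = 0
    run_end = ends[0]
    for i in range(1, n):
        if starts[i] - run_end < max_gap:
            run_end = max(run_end, ends[i])
        else:
            current += 1
            run_end = ends[i]
        ids[i] = current
    return ids


def merge_db_windows(
    results: Sequence[TestResult],
    fdr: float = 0.05,
    max_gap: int = 100,
) -> list[RegionResult]:
    """Summarise the plain sliding-window analysis into regions.

    Windows are BH-adjusted at the window level; those passing the threshold
    are merged single-linkage when separated by less than ``max_gap`` bp *and*
    sharing the direction of fold change.  The FDR semantics remain
    window-level — this is the naive summarisation, provided for comparison
    with the hybrid procedure.
    """
    if not results:
        return []
    pvals = np.array([r.pvalue for r in results])
    qvals = bh_adjust(pvals)
    keep = np.flatnonzero(qvals <= fdr)
    if keep.size == 0:
        return []
    starts = np.array([results[i].feature.start for i in keep])
    ends = np.array([results[i].feature.end for i in keep])
    signs = np.array([1 if results[i].logFC >= 0 else -1 for i in keep])
    order = np.lexsort((starts,))
    keep, starts, ends, signs = keep[order], starts[order], ends[order], signs[order]

    out: list[RegionResult] = []
    # cluster within each sign separately: same-direction rule
    for sign in (-1, 1):
        sel = signs == sign
        if not sel.any():
            continue
        ids = _cluster_sorted(starts[sel], ends[sel], max_gap)
        k_idx = keep[sel]
        s_arr, e_arr = starts[sel], ends[sel]
        for cid in range(ids.max() + 1):
            members = np.flatnonzero(ids == cid)
            midx = [int(k_idx[i]) for i in members]
            chrom = results[midx[0]].feature.chrom
            region = GenomicInterval(chrom, int(s_arr[members].min()), int(e_arr[members].max()))
            best = min(midx, key=lambda i: results[i].pvalue)
            out.append(
                RegionResult(
                    region=region,
                    member_windows=midx,
                    combined_p=float(min(results[i].pvalue for i in midx)),
                    qvalue=float(min(qvals[i] for i in midx)),
                    direction=1 if results[best].logFC >= 0 else -1,
                )
            )
    out.sort(key=lambda r: (r.region.start, r.region.end))
    return out


def hybrid_regions(
    window_results: Sequence[TestResult],
    peak_intervals: Sequence[GenomicInterval],
) -> list[RegionResult]:
    """Simes/BH region-level inference over peak clusters.

    Each called peak defines one cluster containing every window that
    overlaps it; a window overlapping two peaks contributes to both clusters.
    The cluster's combined P-value is the Simes statistic of its member
    window P-values, and BH across clusters controls the region-level FDR.
    Peaks with no overlapping tested window are omitted.
    """
    if not peak_intervals:
        return []
    w_starts = np.array([r.feature.start for r in window_results], dtype=np.int64)
    w_ends = np.array([r.feature.end for r in window_results], dtype=np.int64)
    w_p = np.array([r.pvalue for r in window_results])
    order = np.argsort(w_starts, kind="stable")
    w_starts, w_ends, w_p = w_starts[order], w_ends[order], w_p[order]
    orig_idx = np.asarray(order)
    max_width = int((w_ends - w_starts).max()) if len(w_starts) else 0

    clusters: list[RegionResult] = []
    member_p: list[np.ndarray] = []
    for peak in peak_intervals:
        lo = np.searchsorted(w_starts, peak.start - max_width, "left")
        hi = np.searchsorted(w_starts, peak.end, "left")
        if hi <= lo:
            continue
        sel = np.flatnonzero(w_ends[lo:hi] > peak.start) + lo
        if sel.size == 0:
            continue
        members = [int(orig_idx[i]) for i in sel]
        best = min(members, key=lambda i: window_results[i].pvalue)
        clusters.append(
            RegionResult(
                region=peak,
                member_windows=members,
                combined_p=simes(w_p[sel]),
                direction=1 if window_results[best].logFC >= 0 else -1,
            )
        )
        member_p.append(w_p[sel])
    if clusters:
        qvals = bh_adjust(np.array([c.combined_p for c in clusters]))
        for c, q in zip(clusters, qvals):
            c.qvalue = float(q)
    return clusters


# ---------------------------------------------------------------------------
# Truth-based error metrics
# ---------------------------------------------------------------------------


def _bounds(intervals: Sequence[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([iv.start for iv in intervals], dtype=np.int64),
        np.array([iv.end for iv in intervals], dtype=np.int64),
    )


def observed_fdr_window(
    detected_windows: Sequence[GenomicInterval], truth: TruthTable
) -> float:
    """Fraction of detected windows lying outside DB true-peak regions.

    A window 'lies outside' when it does not overlap any DB region; with no
    detections the convention is 0.
    """
    if not detected_windows:
        return 0.0
    starts, ends = _bounds(detected_windows)
    inside = truth.queries_overlapping_db(starts, ends)
    return float(1.0 - inside.mean())


def observed_fdr_region(
    detected: Sequence[GenomicInterval],
    truth: TruthTable,
    by: str = "true_peaks",
) -> float:
    """Region-level observed FDR against the simulation truth.

    ``by='true_peaks'``: fraction of *detected true peaks* (true peaks
    overlapped by at least one detected interval) that are not DB — the
    definition used when every detection lies inside some true peak.
    ``by='regions'``: fraction of *detected intervals* with no overlap with
    any DB region — the definition used when background detections are
    possible.  0/0 is 0 in both cases.
    """
    if not detected:
        return 0.0
    starts, ends = _bounds(detected)
    if by == "true_peaks":
        hit = truth.overlapping_peaks(starts, ends)
        if hit.size == 0:
            return 0.0
        flags = truth.is_db_flags()[hit]
        return float(1.0 - flags.mean())
    if by == "regions":
        inside = truth.queries_overlapping_db(starts, ends)
        return float(1.0 - inside.mean())
    raise ValueError(f"unknown mode {by!r}")


def power_count(detected: Sequence[GenomicInterval], truth: TruthTable) -> int:
    """Number of DB true peaks overlapped by at least one detected interval."""
    if not detected:
        return 0
    starts, ends = _bounds(detected)
    hit = truth.overlapping_peaks(starts, ends)
    if hit.size == 0:
        return 0
    return int(truth.is_db_flags()[hit].sum())
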