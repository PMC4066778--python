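import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbregions.core import GenomicInterval
from dbregions.dbtest import TestResult as WindowResult
from dbregions.regions import (
    bh_adjust,
    hybrid_regions,
    merge_db_windows,
    observed_fdr_region,
    observed_fdr_window,
    power_count,
    simes,
    simes_grouped,
)
from dbregions.simulate import TruePeak, TruthTable

from conftest import iv

pvals_strategy = st.lists(
    st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=12
)


def brute_force_simes(pvalues):
    """Direct evaluation over all ranks of the combined-P definition."""
    p = sorted(pvalues)
    n = len(p)
    return min(1.0, min(n * p[r] / (r + 1) for r in range(n)))


def brute_force_bh(pvalues):
    """Adjusted P by scanning all rejection thresholds."""
    p = np.asarray(pvalues)
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        # smallest q at which hypothesis i is rejected by step-up BH
        candidates = [
            m * p[j] / (p <= p[j]).sum() for j in range(m) if p[j] >= pi
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestSimes:
    def test_single_pvalue_identity(self):
        assert simes([0.04]) == pytest.approx(0.04)

    def test_hand_computed_example(self):
        assert simes([0.01, 0.04, 0.90]) == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert simes([1.0, 1.0]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            simes([])

    @given(pvals_strategy)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force(self, p):
        assert simes(p) == pytest.approx(brute_force_simes(p))

    @given(pvals_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariant_and_bounded(self, p):
        rng = np.random.default_rng(0)
        shuffled = list(np.array(p)[rng.permutation(len(p))])
        assert simes(p) == pytest.approx(simes(shuffled))
        eps = 1e-9  # n*p/n can round one ulp below p itself
        assert min(p) - eps <= simes(p) <= min(1.0, len(p) * min(p)) + eps

    def test_grouped_matches_scalar(self, rng):
        p = rng.uniform(size=50)
        gid = rng.integers(0, 5, size=50)
        combined = simes_grouped(p, gid, 5)
        for g in range(5):
            assert combined[g] == pytest.approx(simes(p[gid == g]))


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    @given(pvals_strategy)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)


def _result(start, end, pvalue, logfc=1.0):
    return WindowResult(
        feature=iv(start, end), logFC=logfc, aveLogCPM=0.0, F=0.0,
        pvalue=pvalue, df_prior=np.inf, df_residual=2,
    )


class TestMergeDbWindows:
    def test_nearby_same_sign_windows_merge(self):
        res = [_result(0, 10, 1e-6), _result(60, 70, 1e-6)]
        merged = merge_db_windows(res, fdr=0.05, max_gap=100)
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (0, 70)

    def test_opposite_signs_stay_separate(self):
        res = [_result(0, 10, 1e-6, 1.0), _result(60, 70, 1e-6, -1.0)]
        assert len(merge_db_windows(res, fdr=0.05)) == 2

    def test_gap_of_exactly_max_gap_splits(self):
        res = [_result(0, 10, 1e-6), _result(110, 120, 1e-6)]
        assert len(merge_db_windows(res, fdr=0.05, max_gap=100)) == 2

    def test_non_significant_windows_are_dropped(self):
        res = [_result(0, 10, 1e-6), _result(60, 70, 0.9)]
        merged = merge_db_windows(res, fdr=0.05)
        assert len(merged) == 1
        assert merged[0].region.end == 10


class TestHybridRegions:
    def test_simes_per_cluster(self):
        windows = [_result(100, 101, 0.01), _result(150, 151, 0.04), _result(190, 191, 0.90)]
        clusters = hybrid_regions(windows, [iv(50, 250)])
        assert len(clusters) == 1
        assert clusters[0].combined_p == pytest.approx(0.03)
        assert clusters[0].qvalue == pytest.approx(0.03)

    def test_window_in_two_peaks_contributes_to_both(self):
        windows = [_result(100, 200, 0.02)]
        clusters = hybrid_regions(windows, [iv(0, 150), iv(150, 300)])
        assert len(clusters) == 2
        assert all(c.member_windows == [0] for c in clusters)

    def test_peak_without_windows_is_omitted(self):
        windows = [_result(100, 101, 0.5)]
        clusters = hybrid_regions(windows, [iv(50, 150), iv(5000, 5100)])
        assert len(clusters) == 1

    def test_bh_across_clusters(self):
        windows = [_result(100, 101, 0.001), _result(1000, 1001, 0.8), _result(2000, 2001, 0.9)]
        clusters = hybrid_regions(
            windows, [iv(50, 150), iv(950, 1050), iv(1950, 2050)]
        )
        qvals = sorted(c.qvalue for c in clusters)
        assert qvals[0] == pytest.approx(3 * 0.001)  # m * p_s with one rejection


def _truth(db_flags, half=100, spacing=10_000):
    peaks = []
    for i, db in enumerate(db_flags):
        c = (i + 1) * spacing
        peaks.append(
            TruePeak(i, c, (30.0, 10.0) if db else (20.0, 20.0), 0.05, db,
                     iv(c - half, c + half + 1))
        )
    return TruthTable(peaks=peaks, genome_length=(len(db_flags) + 2) * spacing)


class TestTruthMetrics:
    def test_window_fdr_counts_outside_windows(self):
        truth = _truth([True, False])
        # 18 windows inside the DB region, 2 outside any DB region
        detected = [iv(10_000 - 90 + 10 * k, 10_000 - 90 + 10 * k + 10) for k in range(18)]
        detected += [iv(20_000, 20_010), iv(25_000, 25_010)]
        assert observed_fdr_window(detected, truth) == pytest.approx(0.10)

    def test_no_detections_gives_zero(self):
        truth = _truth([True])
        assert observed_fdr_window([], truth) == 0.0
        assert observed_fdr_region([], truth) == 0.0
        assert power_count([], truth) == 0

    def test_region_fdr_true_peak_interpretation(self):
        truth = _truth([True, False])
        # one detected cluster in the DB peak, one in the non-DB peak: half of
        # the detected true peaks are false discoveries
        detected = [iv(9_950, 10_050), iv(19_950, 20_050)]
        assert observed_fdr_region(detected, truth, by="true_peaks") == pytest.approx(0.5)

    def test_region_fdr_region_interpretation_counts_background(self):
        truth = _truth([True, False])
        detected = [iv(9_950, 10_050), iv(55_000, 55_100)]  # one DB hit, one background
        assert observed_fdr_region(detected, truth, by="regions") == pytest.approx(0.5)
        # the true-peak interpretation ignores the background detection
        assert observed_fdr_region(detected, truth, by="true_peaks") == 0.0

    def test_power_counts_db_peaks_per_truth(self):
        truth = _truth([True, True, False])
        spanning = [iv(9_000, 21_000)]  # one region overlapping two DB truths
        assert power_count(spanning, truth) == 2
        assert observed_fdr_window(spanning, truth) == 0.0
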