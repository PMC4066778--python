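import numpy as np
import pytest

from dbregions.core import ExperimentDesign, GenomicInterval
from dbregions.count import count_5prime
from dbregions.simulate import (
    BackgroundConfig,
    SimulationConfig,
    TruePeak,
    TruthTable,
    build_truth,
    place_reads,
    sample_dispersion,
    simulate_background,
    simulate_counts,
    simulate_dataset,
)


class TestSampleDispersion:
    def test_mean_matches_inverse_chisquare(self, rng):
        draws = sample_dispersion(20, rng, size=200_000)
        # E[1/chi2_nu] = 1/(nu - 2)
        assert abs(draws.mean() - 1 / 18) < 5e-4
        assert (draws > 0).all()

    def test_seeded_reproducibility(self):
        a = sample_dispersion(20, np.random.default_rng(3), size=10)
        b = sample_dispersion(20, np.random.default_rng(3), size=10)
        np.testing.assert_array_equal(a, b)

    def test_low_df_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_dispersion(2, rng)


class TestBuildTruth:
    def test_no_db_means_all_x0(self, rng):
        truth = build_truth(SimulationConfig(N=3, x0=20.0), rng)
        assert all(p.mu == (20.0, 20.0) for p in truth.peaks)
        assert truth.db_regions == []

    def test_swap_construction_is_balanced(self, rng):
        cfg = SimulationConfig(N=4, N_db=1, x0=20.0, x1=30.0, x2=10.0)
        truth = build_truth(cfg, rng)
        mus = sorted(p.mu for p in truth.peaks if p.is_db)
        assert mus == [(10.0, 30.0), (30.0, 10.0)]
        assert sum(not p.is_db for p in truth.peaks) == 2

    def test_centres_at_least_spacing_apart(self, rng):
        truth = build_truth(SimulationConfig(N=100, x0=20.0), rng)
        centres = np.array([p.centre for p in truth.peaks])
        assert np.diff(centres).min() >= 10_000

    def test_abundance_independent_of_db(self, rng):
        cfg = SimulationConfig(N=100, N_db=30, x0=20.0, x1=30.0, x2=10.0)
        truth = build_truth(cfg, rng)
        total = {True: [], False: []}
        for p in truth.peaks:
            total[p.is_db].append(sum(p.mu))
        assert np.mean(total[True]) == np.mean(total[False]) == 40.0

    def test_db_mean_constraint_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(N=10, N_db=2, x0=20.0, x1=30.0, x2=15.0)


def _single_peak_truth(mu, phi, n=2000, mode="TF"):
    h = 100 if mode == "TF" else 500
    peaks = [
        TruePeak(i, (i + 1) * 10_000, mu, phi, False,
                 GenomicInterval("chrSim", (i + 1) * 10_000 - h, (i + 1) * 10_000 + h + 1))
        for i in range(n)
    ]
    return TruthTable(peaks=peaks, genome_length=(n + 2) * 10_000)


class TestSimulateCounts:
    def test_poisson_limit_variance(self, rng, two_by_two_design):
        truth = _single_peak_truth((20.0, 20.0), 1e-10, n=20_000)
        cm = simulate_counts(truth, two_by_two_design, rng)
        var = cm.counts[:, 0].var()
        assert abs(var - 20) < 1.5

    def test_nb_variance(self, rng, two_by_two_design):
        truth = _single_peak_truth((20.0, 20.0), 1 / 18, n=50_000)
        cm = simulate_counts(truth, two_by_two_design, rng)
        var = cm.counts[:, 0].var()
        # mu + phi*mu^2 = 20 + 400/18
        assert abs(var - (20 + 400 / 18)) < 2.0

    def test_zero_mean_gives_zero_counts(self, rng, two_by_two_design):
        truth = _single_peak_truth((0.0, 0.0), 1 / 18, n=100)
        cm = simulate_counts(truth, two_by_two_design, rng)
        assert cm.counts.sum() == 0


class TestPlaceReads:
    def test_tf_reads_within_fragment_length_of_centre(self, rng):
        pos, strand = place_reads(
            np.array([5000]), np.array([2001]), "TF", rng, f=100
        )
        assert pos.min() >= 4900 and pos.max() <= 5100
        fwd = pos[strand == 1]
        rev = pos[strand == -1]
        assert fwd.max() <= 5000 and rev.min() >= 5000  # strand bimodality

    def test_tf_even_strand_split(self, rng):
        _, strand = place_reads(np.array([5000]), np.array([10]), "TF", rng, f=100)
        assert (strand == 1).sum() == 5

    def test_histone_support_and_symmetry(self, rng):
        pos, strand = place_reads(
            np.array([50_000]), np.array([200_000]), "histone", rng, hist_width=1000
        )
        assert pos.min() >= 49_500 and pos.max() <= 50_500
        assert abs(pos.mean() - 50_000) < 5
        # strand is independent of position: mean position equal per strand
        assert abs(pos[strand == 1].mean() - pos[strand == -1].mean()) < 10


class TestBackground:
    def test_reads_stay_in_their_blocks_and_mean_rate(self, rng):
        libs = simulate_background(200_000, BackgroundConfig(), 20, rng, n_libraries=2)
        for pos, strand in libs:
            assert pos.min() >= 0 and pos.max() < 200_000
        # expected count per block per library = 30 (U(10,50) midpoint)
        n_blocks = 200_000 // 2000
        mean_per_block = np.mean([len(p) / n_blocks for p, _ in libs])
        assert abs(mean_per_block - 30) < 3


class TestSimulateDataset:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(N=50, N_db=5, x0=20.0, x1=30.0, x2=10.0, seed=9)
        t1, libs1, cm1, _ = simulate_dataset(cfg)
        t2, libs2, cm2, _ = simulate_dataset(cfg)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)
        for a, b in zip(libs1, libs2):
            np.testing.assert_array_equal(a.pos5, b.pos5)
            np.testing.assert_array_equal(a.strand, b.strand)

    def test_read_totals_match_count_matrix_exactly(self):
        cfg = SimulationConfig(N=200, N_db=20, x0=20.0, x1=30.0, x2=10.0, seed=4)
        truth, libs, cm, _ = simulate_dataset(cfg)
        recounted = count_5prime(libs, truth.regions())
        np.testing.assert_array_equal(recounted.counts, cm.counts)

    def test_expected_library_size(self):
        cfg = SimulationConfig(N=2000, x0=20.0, seed=12)
        _, libs, _, _ = simulate_dataset(cfg)
        for lib in libs:
            assert abs(lib.size - 2000 * 20) / (2000 * 20) < 0.05

    def test_counts_recover_group_means(self):
        cfg = SimulationConfig(N=5000, N_db=500, x0=20.0, x1=30.0, x2=10.0, seed=2)
        truth, _, cm, design = simulate_dataset(cfg)
        grp2 = design.group_indicator()
        mu1 = np.array([p.mu[0] for p in truth.peaks])
        up1 = mu1 == 30.0
        obs = cm.counts[np.ix_(up1, ~grp2)].mean()
        assert abs(obs - 30.0) < 0.5
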