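import numpy as np
import pytest

from dbregions.core import CountMatrix, ExperimentDesign, GenomicInterval
from dbregions.dbtest import (
    DispersionTrend,
    ave_log_cpm,
    estimate_trend,
    fit_nb_glm,
    ql_ftest,
)
from dbregions.simulate import SimulationConfig, build_truth, simulate_counts

from conftest import iv


def _cm(rows):
    rows = np.asarray(rows)
    feats = [iv(i * 1000, i * 1000 + 100) for i in range(rows.shape[0])]
    return CountMatrix(feats, [f"lib{j}" for j in range(rows.shape[1])], rows)


def _simulated_cm(n, phi_df=20.0, x0=20.0, seed=0, design=None):
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(N=n, x0=x0, dispersion_df=phi_df, seed=seed)
    truth = build_truth(cfg, rng)
    return simulate_counts(truth, design, rng)


class TestAveLogCpm:
    def test_equal_libraries_match_single_library_value(self):
        cm = _cm([[10, 10]])
        val = ave_log_cpm(cm, np.array([1e6, 1e6]))[0]
        assert val == pytest.approx(np.log2(1e6 * 10.5 / (1e6 + 1)))

    def test_doubling_sizes_lowers_abundance_by_one(self):
        cm = _cm([[10, 10], [100, 100]])
        a1 = ave_log_cpm(cm, np.array([1e6, 1e6]))
        a2 = ave_log_cpm(cm, np.array([2e6, 2e6]))
        np.testing.assert_allclose(a1 - a2, 1.0, atol=0.01)

    def test_zero_counts_are_finite(self):
        cm = _cm([[0, 0]])
        assert np.isfinite(ave_log_cpm(cm, np.array([1e6, 1e6]))).all()


class TestFitNbGlm:
    def test_perfect_fit_has_zero_deviance(self, two_by_two_design):
        rates, dev, df = fit_nb_glm(
            np.array([10, 10, 10, 10]), two_by_two_design, np.full(4, 1e6), 0.05
        )
        assert dev == pytest.approx(0.0, abs=1e-10)
        assert df == 2
        np.testing.assert_allclose(rates, [1e-5, 1e-5])

    def test_group_means_and_positive_deviance(self, two_by_two_design):
        rates, dev, _ = fit_nb_glm(
            np.array([8, 12, 10, 10]), two_by_two_design, np.full(4, 1e6), 0.05
        )
        np.testing.assert_allclose(rates, [1e-5, 1e-5])
        assert dev > 0

    def test_offset_weighted_mean_rate(self):
        design = ExperimentDesign(group=["g1", "g1", "g2"], lib_size=np.ones(3))
        rates, _, _ = fit_nb_glm(
            np.array([10, 20, 5]), design, np.array([1e6, 2e6, 1e6]), 0.0
        )
        assert rates[0] == pytest.approx(30 / 3e6)

    def test_deviance_matches_statsmodels_family(self, two_by_two_design):
        import statsmodels.api as sm

        y = np.array([8, 25, 10, 14])
        eff = np.full(4, 1e6)
        phi = 0.07
        rates, dev, _ = fit_nb_glm(y, two_by_two_design, eff, phi)
        grp2 = two_by_two_design.group_indicator()
        mu = np.where(grp2, rates[1], rates[0]) * eff
        fam = sm.families.NegativeBinomial(alpha=phi)
        assert dev == pytest.approx(fam.deviance(y, mu), rel=1e-8)

    def test_negative_dispersion_rejected(self, two_by_two_design):
        with pytest.raises(ValueError):
            fit_nb_glm(np.ones(4), two_by_two_design, np.full(4, 1e6), -0.1)


class TestEstimateTrend:
    def test_recovers_inverse_chisquare_mean_dispersion(self, two_by_two_design):
        cm = _simulated_cm(5000, seed=1, design=two_by_two_design)
        eff = two_by_two_design.effective_sizes()
        trend = estimate_trend(cm, two_by_two_design, eff)
        abundances = ave_log_cpm(cm, eff)
        vals = np.asarray(trend(abundances))
        assert (vals > 0.03).all() and (vals < 0.09).all()

    def test_near_zero_for_poisson_counts(self, rng, two_by_two_design):
        counts = rng.poisson(50, size=(5000, 4))
        cm = _cm(counts)
        eff = two_by_two_design.effective_sizes()
        trend = estimate_trend(cm, two_by_two_design, eff)
        assert (np.asarray(trend(trend.knots)) <= 0.01).all()

    def test_evaluation_clamps_outside_range(self):
        trend = DispersionTrend(knots=np.array([0.0, 1.0]), values=np.array([0.1, 0.2]))
        assert trend(-5.0) == pytest.approx(0.1)
        assert trend(5.0) == pytest.approx(0.2)

    def test_requires_residual_df(self):
        design = ExperimentDesign(group=["g1", "g2"], lib_size=np.ones(2))
        with pytest.raises(ValueError):
            estimate_trend(_cm([[5, 6]]), design, np.ones(2))


@pytest.fixture(scope="module")
def null_results():
    design = ExperimentDesign(group=["g1", "g1", "g2", "g2"], lib_size=np.full(4, 1e6))
    cm = _simulated_cm(5000, seed=3, design=design)
    cm = cm.subset(cm.row_totals() >= 20)
    eff = design.effective_sizes()
    trend = estimate_trend(cm, design, eff)
    return ql_ftest(cm, design, eff, trend)


class TestQlFtest:
    def test_identical_counts_give_unit_pvalue(self, two_by_two_design):
        counts = np.tile([[10, 10, 10, 10]], (200, 1))
        counts[:100] = np.arange(100)[:, None] + 5  # spread of abundances
        cm = _cm(counts)
        eff = two_by_two_design.effective_sizes()
        trend = DispersionTrend(knots=np.array([0.0, 20.0]), values=np.array([0.05, 0.05]))
        res = ql_ftest(cm, two_by_two_design, eff, trend)
        assert all(r.F == 0 and r.pvalue == 1.0 for r in res)

    def test_strong_db_is_detected(self, rng, two_by_two_design):
        counts = np.column_stack([
            rng.poisson(90, size=(500, 2)), rng.poisson(10, size=(500, 2))
        ])
        cm = _cm(counts)
        eff = two_by_two_design.effective_sizes()
        trend = estimate_trend(cm, two_by_two_design, eff)
        res = ql_ftest(cm, two_by_two_design, eff, trend)
        pv = np.array([r.pvalue for r in res])
        assert (pv < 0.01).mean() > 0.95
        assert all(r.logFC < 0 for r in res)

    def test_null_pvalues_roughly_uniform(self, null_results):
        pv = np.array([r.pvalue for r in null_results])
        assert abs((pv < 0.05).mean() - 0.05) < 0.015
        assert abs((pv < 0.5).mean() - 0.5) < 0.03

    def test_pvalues_within_unit_interval(self, null_results):
        pv = np.array([r.pvalue for r in null_results])
        assert (pv > 0).all() and (pv <= 1).all()

    def test_monotone_in_group_difference(self, two_by_two_design):
        # fixed within-group counts, growing between-group difference
        eff = two_by_two_design.effective_sizes()
        trend = DispersionTrend(knots=np.array([0.0, 20.0]), values=np.array([0.05, 0.05]))
        base = np.array([[50, 50, 50, 50]])
        pvals = []
        for delta in (0, 5, 10, 20, 40):
            counts = base.copy()
            counts[0, 2:] += delta
            filler = np.tile([[40, 60, 45, 55]], (300, 1))  # stabilises the EB fit
            cm = _cm(np.vstack([counts, filler]))
            res = ql_ftest(cm, two_by_two_design, eff, trend)
            pvals.append(res[0].pvalue)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_exchangeable_under_library_permutation(self, two_by_two_design, rng):
        counts = rng.poisson(30, size=(400, 4))
        eff = np.array([1e6, 1.1e6, 0.9e6, 1e6])
        perm = [2, 0, 3, 1]
        design_p = ExperimentDesign(
            group=[two_by_two_design.group[i] for i in perm], lib_size=eff[perm]
        )
        cm = _cm(counts)
        cm_p = CountMatrix(cm.features, [cm.libraries[i] for i in perm], counts[:, perm])
        trend = DispersionTrend(knots=np.array([0.0, 20.0]), values=np.array([0.05, 0.05]))
        res = ql_ftest(cm, two_by_two_design, eff, trend)
        res_p = ql_ftest(cm_p, design_p, eff[perm], trend)
        np.testing.assert_allclose(
            [r.pvalue for r in res], [r.pvalue for r in res_p], rtol=1e-10
        )
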