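"""Negative-binomial quasi-likelihood testing for two-group count data.

Per feature, counts follow NB(mu, phi) with variance ``mu + phi*mu**2``.  An
abundance-dependent trend is fitted to the NB dispersions by maximising the
Cox-Reid adjusted profile likelihood within abundance bins and smoothing the
bin estimates.  Each feature's residual deviance at the trended dispersion
yields a quasi-dispersion; these are squeezed towards an abundance-dependent
prior with empirical-Bayes moment matching (robust to outliers via
winsorisation), and the group effect is tested with a quasi-likelihood F
statistic whose denominator degrees of freedom are inflated by the estimated
prior df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import CountMatrix, ExperimentDesign, GenomicInterval

_PRIOR_COUNT = 0.5
_MIN_PVALUE = 1e-300
_PHI_FLOOR = 1e-6


@dataclass
class DispersionTrend:
    """Piecewise-linear NB dispersion as a function of average log2 CPM.

    Evaluation outside the knot range clamps to the endpoint values.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if (self.values <= 0).any():
            raise ValueError("trend values must be positive")

    def __call__(self, abundance: np.ndarray | float) -> np.ndarray | float:
        return np.interp(abundance, self.knots, self.values)


@dataclass
class TestResult:
    feature: GenomicInterval
    logFC: float
    aveLogCPM: float
    F: float
    pvalue: float
    df_prior: float
    df_residual: float


def ave_log_cpm(cm: CountMatrix, eff_sizes: np.ndarray) -> np.ndarray:
    """Average log2 counts-per-million, combined on the count scale.

    A prior count of 0.5 (with the matching 2x prior adjustment of the
    library size) keeps zero counts finite.
    """
    eff = np.asarray(eff_sizes, dtype=float)
    cpm = 1e6 * (cm.counts + _PRIOR_COUNT) / (eff + 2 * _PRIOR_COUNT)
    return np.log2(cpm.mean(axis=1))


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorised over features x libraries)
# ---------------------------------------------------------------------------


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-feature NB residual deviance summed over libraries.

    ``phi`` may be a scalar or per-feature vector; ``phi=0`` falls back to
    the Poisson deviance.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = special.xlogy(y, y / mu)
        pois = term1 - (y - mu)
        r = 1.0 / np.maximum(phi, 1e-300)
        nb = term1 - (y + r) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        unit = np.where(phi > 0, nb, pois)
    return 2.0 * unit.sum(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB log-likelihood summed over libraries (constant terms
    in y dropped are NOT dropped: gammaln(y+1) is omitted since it cancels
    when comparing dispersions)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    r = 1.0 / max(phi, _PHI_FLOOR)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        + special.xlogy(y, mu / (r + mu))
        + r * np.log(r / (r + mu))
    )
    return ll.sum(axis=1)


def _fit_group_rates(
    counts: np.ndarray, grp2: np.ndarray, eff_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form fitted rates per group: offset-weighted mean rate.

    Returns (rate1, rate2) arrays; the fitted mean for library ``i`` is its
    group's rate times the library's effective size.
    """
    eff = np.asarray(eff_sizes, dtype=float)
    r1 = counts[:, ~grp2].sum(axis=1) / eff[~grp2].sum()
    r2 = counts[:, grp2].sum(axis=1) / eff[grp2].sum()
    return r1, r2


def fit_nb_glm(
    counts_row: np.ndarray,
    design: ExperimentDesign,
    eff_sizes: np.ndarray,
    dispersion: float,
) -> tuple[np.ndarray, float, int]:
    """Fit the two-group NB model with log link and library-size offsets.

    Returns (group rates, residual deviance, residual df).  The group rate is
    the offset-weighted mean ``sum(y)/sum(size)`` over the group's libraries.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    y = np.asarray(counts_row, dtype=float)[None, :]
    grp2 = design.group_indicator()
    eff = np.asarray(eff_sizes, dtype=float)
    r1, r2 = _fit_group_rates(y, grp2, eff)
    mu = np.where(grp2, r2[:, None] * eff, r1[:, None] * eff)
    dev = float(_nb_deviance(y, mu, np.array([dispersion]))[0])
    return np.array([r1[0], r2[0]]), dev, design.n_libraries - 2


# ---------------------------------------------------------------------------
# Dispersion trend
# ---------------------------------------------------------------------------


def _adjusted_profile_loglik(
    y: np.ndarray, mu: np.ndarray, grp2: np.ndarray, phi: float
) -> np.ndarray:
    """Cox-Reid adjusted per-feature profile log-likelihood at dispersion phi.

    For the two-group one-factor design the information matrix is block
    diagonal, so the adjustment is half the log of each group's summed
    working weight ``mu/(1 + phi*mu)``.
    """
    ll = _nb_loglik(y, mu, phi)
    w = mu / (1.0 + phi * mu)
    cr = 0.5 * (
        np.log(np.maximum(w[:, ~grp2].sum(axis=1), 1e-10))
        + np.log(np.maximum(w[:, grp2].sum(axis=1), 1e-10))
    )
    return ll - cr


def estimate_trend(
    cm: CountMatrix,
    design: ExperimentDesign,
    eff_sizes: np.ndarray,
    n_bins: int = 50,
    span: float = 0.5,
) -> DispersionTrend:
    """Estimate the abundance-dependent NB dispersion trend.

    Features are grouped into equal-occupancy abundance bins; within each bin
    the common dispersion maximising the Cox-Reid adjusted profile likelihood
    is located by a two-stage grid search on log-dispersion, and the bin
    estimates are smoothed by local regression on the log scale.
    """
    if design.n_libraries - 2 < 1:
        raise ValueError("at least one residual degree of freedom required")
    y = cm.counts.astype(float)
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty count matrix")
    eff = np.asarray(eff_sizes, dtype=float)
    grp2 = design.group_indicator()
    abundance = ave_log_cpm(cm, eff)
    r1, r2 = _fit_group_rates(y, grp2, eff)
    mu = np.where(grp2, r2[:, None] * eff, r1[:, None] * eff)

    n_bins = max(1, min(n_bins, n // 2 if n >= 4 else 1))
    order = np.argsort(abundance, kind="stable")
    bin_ids = np.empty(n, dtype=np.int64)
    bin_ids[order] = (np.arange(n) * n_bins) // n

    # stage 1: coarse grid over all features at once
    coarse = np.exp(np.linspace(math.log(_PHI_FLOOR), math.log(5.0), 25))
    apl_bins = np.empty((len(coarse), n_bins))
    for k, phi in enumerate(coarse):
        apl = _adjusted_profile_loglik(y, mu, grp2, float(phi))
        apl_bins[k] = np.bincount(bin_ids, weights=apl, minlength=n_bins)
    best = apl_bins.argmax(axis=0)

    # stage 2: fine grid around each bin's coarse optimum
    log_coarse = np.log(coarse)
    step = log_coarse[1] - log_coarse[0]
    phi_hat = np.empty(n_bins)
    for b in range(n_bins):
        centre = log_coarse[best[b]]
        fine = np.exp(np.linspace(centre - step, centre + step, 13))
        rows = bin_ids == b
        yb, mub = y[rows], mu[rows]
        vals = [
            _adjusted_profile_loglik(yb, mub, grp2, float(p)).sum() for p in fine
        ]
        phi_hat[b] = fine[int(np.argmax(vals))]

    bin_abund = np.bincount(bin_ids, weights=abundance, minlength=n_bins) / np.maximum(
        np.bincount(bin_ids, minlength=n_bins), 1
    )
    if n_bins >= 4:
        sm = lowess(
            np.log(phi_hat), bin_abund, frac=span, it=2, return_sorted=True
        )
        knots, logvals = sm[:, 0], sm[:, 1]
        knots, idx = np.unique(knots, return_index=True)
        logvals = logvals[idx]
    else:
        knots, logvals = bin_abund, np.log(phi_hat)
        order = np.argsort(knots)
        knots, logvals = knots[order], logvals[order]
    return DispersionTrend(knots=knots, values=np.maximum(np.exp(logvals), _PHI_FLOOR))


# ---------------------------------------------------------------------------
# Empirical-Bayes moment matching for the quasi-dispersions
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _log_f_bias(df1: float, d0: float) -> float:
    """Mean of ``log F(df1, d0)``: the bias of ``E[log s2]`` vs ``log s0^2``."""
    bias = float(special.digamma(df1 / 2.0) - math.log(df1 / 2.0))
    if math.isfinite(d0):
        bias -= float(special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return bias


def _winsorized_logf_var(df1: float, d0: float, trim: float, k: int = 512) -> float:
    """Variance of ``log F(df1, d0)`` after winsorising at the trim quantiles,
    computed on a mid-point quantile grid (exact as k grows)."""
    u = (np.arange(k) + 0.5) / k
    if math.isfinite(d0):
        z = np.log(stats.f.ppf(u, df1, d0))
    else:
        z = np.log(stats.chi2.ppf(u, df1) / df1)
    lo, hi = np.quantile(z, [trim, 1.0 - trim])
    return float(np.var(np.clip(z, lo, hi)))


def _fit_f_dist_robust(
    s2: np.ndarray, df1: float, abundance: np.ndarray, span: float = 0.5,
    trim: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Match an abundance-trended scaled F distribution to quasi-dispersions.

    Models ``s2 ~ s0^2(A) * F(df1, d0)``.  Returns the per-feature prior
    value ``s0^2(A)`` and the prior degrees of freedom ``d0`` (``inf`` when
    the quasi-dispersions show no excess scatter).  The location trend is a
    plain local-regression mean of ``log s2`` on abundance (zero
    quasi-dispersions are excluded from fitting but still squeezed later);
    the scatter is measured as the 5%/95%-winsorised residual variance and
    matched against the exact winsorised variance of ``log F(df1, d0)`` by
    bisection, which makes a handful of outlier quasi-dispersions unable to
    destroy the prior-df estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    z = np.log(s2[pos])
    a = abundance[pos]
    n = z.size
    if n < 3:
        return np.full(s2.size, max(float(s2.mean()), 1e-10)), math.inf
    if n >= 10 and np.ptp(a) > 0:
        sm = lowess(
            z, a, frac=span, it=0, return_sorted=True,
            delta=0.01 * (a.max() - a.min()),
        )
        xs, idx = np.unique(sm[:, 0], return_index=True)
        ztrend_all = np.interp(abundance, xs, sm[:, 1][idx])
        ztrend = np.interp(a, xs, sm[:, 1][idx])
    else:
        ztrend_all = np.full(s2.size, float(z.mean()))
        ztrend = ztrend_all[pos]
    e = z - ztrend
    lo, hi = np.quantile(e, [trim, 1.0 - trim])
    var_w = float(np.var(np.clip(e, lo, hi)))

    # solve var_w = winsorised-var of log F(df1, d0) for d0 (decreasing in d0)
    v_inf = _winsorized_logf_var(df1, math.inf, trim)
    if var_w <= v_inf:
        d0 = math.inf
    else:
        lo_ld, hi_ld = math.log(0.1), math.log(1e6)
        if var_w >= _winsorized_logf_var(df1, math.exp(lo_ld), trim):
            d0 = math.exp(lo_ld)
        else:
            for _ in range(60):
                mid = 0.5 * (lo_ld + hi_ld)
                if _winsorized_logf_var(df1, math.exp(mid), trim) > var_w:
                    lo_ld = mid
                else:
                    hi_ld = mid
            d0 = math.exp(0.5 * (lo_ld + hi_ld))
    return np.exp(ztrend_all - _log_f_bias(df1, d0)), d0


def ql_ftest(
    cm: CountMatrix,
    design: ExperimentDesign,
    eff_sizes: np.ndarray,
    trend: DispersionTrend,
    robust: bool = True,
) -> list[TestResult]:
    """Quasi-likelihood F-test for a group effect at each feature.

    The full (two-mean) and null (one-mean) NB models are fitted at the
    trended dispersion; the deviance drop on 1 df is divided by the
    empirical-Bayes-shrunken quasi-dispersion and referred to an F
    distribution with ``1`` and ``d0 + df_residual`` degrees of freedom
    (a scaled chi-squared when ``d0`` is infinite).
    """
    y = cm.counts.astype(float)
    n, n_lib = y.shape
    df_res = n_lib - 2
    if df_res < 1:
        raise ValueError("quasi-dispersion needs at least one residual df")
    eff = np.asarray(eff_sizes, dtype=float)
    grp2 = design.group_indicator()
    abundance = ave_log_cpm(cm, eff)
    phi = np.asarray(trend(abundance), dtype=float)

    r1, r2 = _fit_group_rates(y, grp2, eff)
    mu_full = np.where(grp2, r2[:, None] * eff, r1[:, None] * eff)
    r0 = y.sum(axis=1) / eff.sum()
    mu_null = r0[:, None] * eff
    dev_full = _nb_deviance(y, mu_full, phi)
    dev_null = _nb_deviance(y, mu_null, phi)
    dev_diff = np.maximum(dev_null - dev_full, 0.0)

    s2 = np.maximum(dev_full, 0.0) / df_res
    if robust:
        s0, d0 = _fit_f_dist_robust(s2, float(df_res), abundance)
    else:
        s0, d0 = _fit_f_dist_plain(s2, float(df_res), abundance)
    if math.isfinite(d0):
        s2_shrunk = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    else:
        s2_shrunk = s0
        df_total = math.inf
    s2_shrunk = np.maximum(s2_shrunk, 1e-10)
    fstat = dev_diff / s2_shrunk
    if math.isfinite(df_total):
        pvals = stats.f.sf(fstat, 1, df_total)
    else:
        pvals = stats.chi2.sf(fstat, 1)
    pvals = np.clip(pvals, _MIN_PVALUE, 1.0)
    pvals[dev_diff == 0.0] = 1.0

    logfc = np.log2(
        ((y[:, grp2].sum(axis=1) + _PRIOR_COUNT) / (eff[grp2].sum() + 1.0))
        / ((y[:, ~grp2].sum(axis=1) + _PRIOR_COUNT) / (eff[~grp2].sum() + 1.0))
    )
    return [
        TestResult(
            feature=cm.features[i],
            logFC=float(logfc[i]),
            aveLogCPM=float(abundance[i]),
            F=float(fstat[i]),
            pvalue=float(pvals[i]),
            df_prior=float(d0),
            df_residual=float(df_res),
        )
        for i in range(n)
    ]


def _fit_f_dist_plain(
    s2: np.ndarray, df1: float, abundance: np.ndarray, span: float = 0.5
) -> tuple[np.ndarray, float]:
    """Non-robust variant of the scaled-F moment matching (no winsorising)."""
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    z = np.log(s2[pos])
    a = abundance[pos]
    n = z.size
    if n < 3:
        return np.full(s2.size, max(float(s2.mean()), 1e-10)), math.inf
    if n >= 10 and np.ptp(a) > 0:
        sm = lowess(
            z, a, frac=span, it=0, return_sorted=True,
            delta=0.01 * (a.max() - a.min()),
        )
        xs, idx = np.unique(sm[:, 0], return_index=True)
        ztrend_all = np.interp(abundance, xs, sm[:, 1][idx])
        ztrend = np.interp(a, xs, sm[:, 1][idx])
    else:
        ztrend_all = np.full(s2.size, float(z.mean()))
        ztrend = ztrend_all[pos]
    e = z - ztrend
    var_e = float(np.var(e, ddof=1)) if n > 1 else 0.0
    evar = var_e - float(special.polygamma(1, df1 / 2.0))
    d0 = 2.0 * _trigamma_inverse(evar) if evar > 0 else math.inf
    return np.exp(ztrend_all - _log_f_bias(df1, d0)), d0


def pvalues(results: list[TestResult]) -> np.ndarray:
    return np.array([r.pvalue for r in results])
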