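# Methods

## The inference problem

ChIP-seq differential binding (DB) analysis asks where protein–DNA binding
changes between two biological conditions. Reads must first be summarised
into counts over genomic features, and the choice of feature — called peaks,
sliding windows, or hybrid peak clusters — changes the error rate that is
actually controlled. Two failure modes motivate this package:

1. **Data snooping in peak-based analyses.** If the intervals to be tested
   are defined using the same between-group contrast that the test measures
   (e.g. two-sample peak calling between conditions), the null distribution
   of the test statistic is distorted and type-I error control is lost.
   Calling peaks on the *pooled* data from all libraries keeps the feature
   definition approximately independent of the DB test.
2. **Window-level vs region-level FDR.** Applying Benjamini–Hochberg (BH)
   across overlapping windows controls the proportion of false *windows*.
   A strongly differential region contributes many detected windows and a
   false region few, so the proportion of false *regions* — the unit on
   which follow-up is done — is systematically larger and is not
   controlled.

The hybrid procedure restores region-level control: windows overlapping a
(pooled-data) peak form a cluster, the member window P-values are combined
with Simes' statistic `p_s = min_r { n p_(r) / r }`, which tests the global
null that no window in the cluster is differential, and BH is applied across
clusters.

## Count model and differential test

Counts for feature *g*, library *i* in group *j* are modelled as negative
binomial with mean `mu_gj * s_i` (with `s_i` the effective library size) and
dispersion `phi_g`, i.e. variance `mu + phi mu^2`.

* **Dispersion trend.** Features are grouped into up to 50 equal-occupancy
  bins by average log2 CPM (aveLogCPM, prior count 0.5, combined on the
  count scale across libraries). Within each bin the common dispersion
  maximising the Cox–Reid adjusted profile likelihood is found by a
  two-stage grid search on log dispersion over [1e-6, 5]; for the two-group
  design the CR adjustment is half the log of each group's summed working
  weights `mu/(1+phi mu)`. Bin estimates are smoothed by unweighted local
  regression (span 0.5) on the log scale, giving a piecewise-linear trend
  clamped at its endpoints. On data generated with dispersions
  1/chi-squared(20) (mean 1/18 ≈ 0.056) the fitted trend stays within
  [0.03, 0.09]; on Poisson data it collapses to ≤ 0.01.
* **Model fit.** With a one-factor two-group design and log link, the NB
  MLE of each group mean is closed-form — the offset-weighted mean rate
  `sum(y)/sum(s)` over the group's libraries — so no IRLS is needed.
  Residual df is `n_libraries − 2`.
* **Quasi-likelihood F-test.** The quasi-dispersion is
  `s²_g = deviance(full model at trended dispersion) / df_residual`.
  Quasi-dispersions are squeezed towards an abundance-dependent prior by
  empirical Bayes: model `s² ~ s0²(A)·F(df_residual, d0)`; the location
  trend of `log s²` on abundance is a plain lowess mean (features with zero
  deviance are excluded from fitting but still squeezed), and `d0` is found
  by matching the 5%/95%-winsorised residual variance to the exact
  winsorised variance of `log F(df_residual, d0)` (bisection; infinite `d0`
  when there is no excess scatter). Winsorisation makes the fit robust to
  outlier quasi-dispersions; matching the winsorised variance of the exact
  log-F reference rather than a normal approximation matters because
  `log chi²_2` is strongly left-skewed — a normal-theory correction makes
  the test visibly conservative. The test statistic is the one-df deviance
  difference divided by the squeezed quasi-dispersion, referred to
  `F(1, d0 + df_residual)` (a chi-squared when `d0` is infinite). P-values
  are floored at 1e-300; a feature with identical fitted means has F = 0
  and P = 1. Under the null simulation this pipeline rejects at
  0.010/0.049/0.099 for nominal 0.01/0.05/0.10.

## Normalization

Composition bias is estimated by trimmed-mean-of-M-values on counts in
10 kbp bins (large bins give stable counts and equal genomic
representation), with **no precision weighting**: after dropping bins with a
zero count in either member of a pair, 30% of each M tail and 5% of each A
tail are trimmed and the factor is 2^(plain mean of surviving M), rescaled
to geometric mean one. The 30%-per-tail trim tolerates up to 30% of bins
differential in one direction (60% when balanced). The reference library is
the one whose upper-quartile count/size ratio is closest to the mean. In all
simulations factors are unity (the balanced DB spike-ins introduce no
composition bias) and effective library sizes equal raw sizes.

## Peak caller

A deliberately simple Poisson scan plays the role a general-purpose caller
such as MACS would play in a real-data pipeline (run without model
building): 5' ends are shifted by half the fragment length
`f` toward the fragment midpoint; windows of width `f` at `f/4` steps are
scored by the upper-tail Poisson probability of the window count at rate
max(genome-wide, local 10-kbp) shifted-read density × window width; windows
with P ≤ 0.1 are merged when overlapping or adjacent, and each merged peak
is re-scored as a whole region (total count vs the local rate scaled to the
peak width). Region-level scoring, rather than best-window scoring, is what
makes the peak score reflect aggregate enrichment instead of placement
noise. Peaks with P > 1e-5 (the conventional default cutoff) are dropped
unless the caller is asked otherwise. The two-sample variant rates each
query range by the control's density — the maximum over the range itself
and 1 kbp / 10 kbp neighbourhoods, scaled by the library-size ratio and
floored at the control's genome-wide rate — so its score is driven by the
treatment/control contrast. No duplicate collapsing is ever performed.

Seven consolidation strategies summarise per-library or per-group peak sets
into one list: peaks are matched across units by single-linkage interval
overlap; a unit with no overlapping call contributes a peak-calling P-value
of 1; the consolidated value is the minimum (union), maximum (intersection)
or second-smallest (at-least-two) of the per-unit values, the smaller
directional value for two-sample union, or the single pooled value. The
threshold tau is set so a fixed number C of peaks is retained, making
strategies comparable at equal list size.

## Synthetic data generator

The generator emulates a replicated two-group ChIP-seq experiment on one
artificial chromosome:

* `N` binding sites at exactly 10 kbp spacing (centres `c_i = (i+1)·10 kbp`,
  genome length `(N+2)·10 kbp`) — a deterministic layout satisfying the
  minimum-separation condition and simplifying bin edges.
* Per-site fragment counts: NB with mean `x0` (non-DB) and dispersion
  `1/chi-squared(20)` per site (mean 1/18), the unscaled reciprocal read of
  "inverse chi-squared". DB is spiked in balanced pairs: `N'` sites get
  means `(x1, x2)`, another `N'` the swap, with `x1 + x2 = 2·x0` so
  abundance is independent of DB status and no composition bias arises.
* Read placement: TF mode splits reads evenly between strands (odd
  remainders randomised) and draws forward 5' ends at `round(c − fX)`,
  reverse at `round(c + fX)`, `X ~ Beta(2,2)`, `f = 100` — the strand
  bimodality of point-source binding. Histone mode places 5' ends at
  `round(c + w(X − 1/2))` with `w = 1000` and strand independent of
  position. Continuous draws are rounded to the nearest base (unbiased for
  symmetric densities); positions are clamped to the chromosome.
* Optional background: contiguous 2-kbp blocks with means U(10, 50) and
  inverse-chi-squared dispersions drawn once and shared by all libraries
  (so background is never DB), reads uniform within the block. Background
  is only generated for the performance study; the type-I and FDR studies
  use none.

What the generator does **not** emulate: sequence-level artefacts (no
FASTQ/mapping, GC or mappability bias), composition bias, irregular peak
spacing or width heterogeneity, paired-end fragments. Passing tests
therefore demonstrate the statistical error-control properties of the
pipeline under a correctly specified NB model, not robustness to alignment
or bias artefacts in real data.

## Simulation studies

All studies use 2 replicates per group, share each iteration's simulated
data across all compared methods (a paired design — per-iteration
differences are not diluted by simulation noise), derive iteration seeds as
`seed + iteration`, and report means with standard errors across
iterations.

1. **Type-I error** (TF, `x0 = 20`, no DB): each consolidation strategy's
   retained peaks are re-mapped to the true peaks they overlap; 5' ends are
   counted over the *true* intervals (so width differences between
   strategies cannot confound the comparison), filtered at total count 20
   (the abundance filter is off for simulated data), and tested; the
   observed error is the fraction of P-values below each threshold. The
   reference analysis tests 10 000 randomly sampled true peaks.
2. **FDR control** (`x0 = 50, x1 = 90, x2 = 10`): the sliding-window
   analysis (1 bp TF / 150 bp histone windows, fragment-extension
   counting) is BH-thresholded at 0.05 and scored by both the window-level
   FDR (detected windows outside DB regions) and the region-level FDR
   (detected true peaks that are not DB); the hybrid analysis tests only
   windows overlapping a pooled-data peak and is scored region-level.
3. **Performance** (weak peaks, background on): the peak-based method
   (pooled calling, 5' counts over *empirical* peak intervals — boundary
   imprecision and background contamination are the phenomena under study)
   and the hybrid approach (spacing 50 bp) are compared at FDR 0.05 on the
   region-centric observed FDR (detections with no DB overlap) and power
   (DB true peaks overlapped by a detection).

### Problem sizes

The packaged test suite runs the studies at reduced scale — type-I at
N = 20 000 with 5 iterations, FDR at N = 5 000 (histone, 25 bp spacing,
5 iterations), performance at N = 5 000 with 4 iterations — chosen so the
Monte-Carlo standard errors are small relative to the effects being
demonstrated while the whole suite stays fast. `scripts/acceptance.py` runs
the type-I study at full width (N = 50 000, C = 10 000) with 5 iterations,
because the strategy-contrast magnitudes depend on the retention fraction
C/N. The `dbregions experiment` command exposes `--preset quick|full`.

## Numerical choices and edge cases

* 0-based half-open coordinates everywhere; adjacency is not overlap.
* NB deviance uses `xlogy` for the `y log(y/mu)` term (0 at y = 0) and
  falls back to the Poisson deviance at dispersion 0; fitted means are
  floored at 1e-12.
* Dispersion grid spans [1e-6, 5]; trend values are floored at 1e-6.
* FDR metrics define 0/0 = 0.
* A region's direction is the sign of its most significant member window's
  log fold change; window-level log fold changes use a prior count of 0.5.
* Consolidation ties at tau are broken by genomic position so that exactly
  C peaks are retained deterministically.

## Known limitations

* The caller is an emulation: it reproduces the *contrasts* between
  calling strategies (near-nominal for pooled calling, deflated for
  intersections, inflated for group-union, grossly inflated for two-sample
  calling), but the exact inflation magnitude of the two-sample strategy
  depends on internals of the program it stands in for and comes out more
  extreme here (few, strongly contrast-selected calls rather than many,
  weakly selected ones).
* Only one-factor two-group designs are supported; no GLM beyond the
  closed-form two-group fit, no exact NB tests.
* Window/bin counting assumes a single-chromosome genome description when
  given an integer length; multi-chromosome inputs are supported via
  `{chrom: length}` mappings, and 5'-interval counting is fully general.
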