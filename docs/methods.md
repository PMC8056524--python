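# Methods

`amytrial` implements a power-analysis pipeline for anti-amyloid prevention
trials whose endpoint is the annualized rate of change of an amyloid-PET
metric, together with the quantification and longitudinal-modelling stages
that produce that endpoint and a synthetic-cohort generator that makes every
stage testable without access to the underlying imaging data.

## Trial power model

The design is a 1:1 randomized placebo-controlled trial read out by the
difference in mean annualized % change between arms. The treatment is assumed
to reduce the group mean rate `mu` by a fraction `f` (default 0.20) while
leaving the between-subject standard deviation `sigma` unchanged, giving the
detectable difference `delta = f * mu`. Power for the two-sided two-sample
t-test with `n` subjects per arm is computed exactly from the noncentral t
distribution with `2n - 2` degrees of freedom and noncentrality
`delta / (sigma * sqrt(2/n))`; `required_n_per_arm` returns the smallest
integer `n` whose power reaches the target (default 0.80 at alpha = 0.05) by
bracketing and bisection, asserting `power(n-1) < target <= power(n)` on
every call. The noncentral-t form matters: a normal approximation is off by
one subject for the large low-burden scenarios. Groups with non-positive mean
rates are rejected — a "20% reduction" of a decline is not a meaningful
anti-amyloid design.

Scenario tables cross three baseline-burden inclusion windows (Centiloid
CL > 20.1; 20.1 < CL <= 49.4; CL <= 20.1) with metric (SUVR/DVR), composite
ROI (cortical/early) and population (all / APOE-e4 carriers only). The
pooled CL > 20.1 group is always summarized from the pooled subject set, not
by merging the two strata's summary statistics. A "table-only" mode feeds
published group summaries (bundled, 48 records) directly into the solver,
bypassing simulation entirely.

## Quantification layer

Target kinetics follow the simplified reference tissue model (SRTM),

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) \int_0^t C_R(u) e^{-k2a (t-u)} du,

with `k2a = k2/(1+BPND)` and `DVR = 1 + BPND`. Reference input curves are
bi-exponential `A (e^{-l1 t} - e^{-l2 t})` with PIB-cerebellum-like defaults
(`l1 = 0.025/min`, `l2 = 0.60/min`, peak ~5.5 min). The convolution runs on
a 1-second grid via an exact first-order IIR recursion; frame averages use
cumulative Simpson integration, so identity kinetics (`R1 = 1, BPND = 0`)
reproduce the reference to ~1e-9 relative.

* **SUVR**: duration-weighted target/reference ratio over 30–60 min p.i.
* **DVR**: reference Logan regression of normalized cumulative target
  activity on normalized cumulative reference activity over frames with
  mid-time >= t\* = 30 min, by unweighted OLS; the `C_R/k2'` abscissa term is
  off by default and available via `k2_ref` (both conventions exist in
  production pipelines). Cumulative integrals are trapezoidal on frame
  mid-times with an implicit origin. On noiseless SRTM curves (0–90 min
  schedule) the slope recovers `1 + BPND` to ~0.15%.
* **Frame schedule** defaults to 4x0.5, 4x1, 2x3, 8x5, 2x4 min (0–60 min;
  the 2x4 extension completes the hour), extended with 5-min frames for
  longer acquisitions. Published protocols rarely print framing; it is
  configuration, and none of the quantities computed here are sensitive to
  it at the tested tolerances.
* **Composites**: cortical = frontal, parietal, temporal, precuneus; early =
  isthmus cingulate, precuneus, lateral orbitofrontal; volume-weighted means
  with equal weights by default (true FreeSurfer volumes can be supplied).
* **Centiloid**: affine SUVR map with default anchors (1.01, 1.90), chosen
  so the published stratum medians land inside their strata; the cohort's
  true conversion is site-specific and therefore configurable. Strata:
  low CL <= 20.1 < intermediate <= 49.4 < high.

With these kinetics SUVR(30–60) always exceeds the equilibrium DVR for
PIB-like parameters (k2 in 0.1–0.2/min) — the late static window samples the
transient overshoot — reproducing the well-known proportional SUVR
overestimation that motivates dynamic acquisition.

## Longitudinal model

Accumulation is estimated by a linear mixed-effects model `value ~ time` with
correlated subject-level random intercepts and slopes, fitted by maximum
likelihood (ML, not REML, so AIC comparisons across fixed-effect structures
remain valid). Per-subject estimates are the empirical-Bayes (shrunken)
predictions; annualized % change is `100 * slope / intercept`, normalizing by
the model-estimated baseline rather than the noisy first observation. The
optimizer cascade (Powell, then L-BFGS, then the default) exists because
quasi-Newton methods often stall on the near-boundary variance components
typical of 2–3 scans per subject; if nothing converges the model falls back
to per-subject OLS, flagged `ols_fallback` and warned, never silently.
Exactly-linear (zero-noise) inputs are detected up front: variance components
are then unidentifiable and per-subject OLS is the correct limit. Group
summaries report the sample mean, SD (n−1) and mean/SD effect size over the
empirical-Bayes per-subject values. (Published tables of this kind sometimes
print effect sizes that do not equal mean/SD — e.g. 1.06/1.30 alongside 0.76;
this package always reports mean/SD.)

## Test-retest cutoffs and accumulators

For a scan pair (T, R), `TRT% = |T - R| / (0.5 |T + R|) * 100`. Cohort TRT%
is the mean over subjects per metric/ROI, computed for the full TRT set and
for its cognitively unimpaired subset; the CU-only mean is the default
accumulator cutoff (the population most comparable to a prevention-trial
cohort), with the all-diagnoses mean as a sensitivity option. A subject is an
accumulator iff annualized % change is strictly above the cutoff; ties are
non-accumulators. The aggregate across TRT subjects is the mean (the usual
choice; configurable, since small TRT studies are sensitive to it).

## Synthetic cohort generator

The generator emulates the structure of a 237-subject cognitively unimpaired
longitudinal PIB cohort: stratum proportions 194/20/23 (low/intermediate/
high), APOE-e4 carrier fractions per stratum (24.8%/75%/65.2%), 2.5 ± 0.6
scans per subject (clipped to 2–5), 4.8 ± 2.1 years first-to-last (clipped
to 1–9.6), stratum-specific age and sex composition.

* **Baseline burden**: per-stratum truncated log-normal Centiloid draws
  (medians 7/35/70, right-skewed as in the published IQRs; the high stratum
  is truncated at 100 CL, which CU cohorts rarely exceed and which keeps the
  rate curve inside its anchored range). Carriers' distribution is shifted
  upward by a log-shift of 0.30 — APOE-e4 affects baseline, not rate,
  mirroring the finding that carriership predicted rates only through the
  biased SUVR metric. Baseline CL maps to cortical DVR through the Centiloid
  anchors and the SUVR bias model below.
* **Rate curve**: true annual % change of cortical DVR is
  `a CL^2 + b CL + c + N(0, sd_stratum)`, the quadratic through the three
  stratum anchors (7, 0.49), (35, 2.34), (70, 1.55) %/yr with stratum SDs
  0.96/0.72/0.93 — the inverted-U with its peak in the intermediate stratum.
  The curve input is clipped at 100 CL, and decline rates are bounded so no
  metric's trajectory goes non-positive within the scan span.
* **Regions**: six atlas regions carry fixed specific-signal multipliers
  (cortical members average exactly 1, early members 1.3). All regions share
  one specific-signal growth rate per subject, so the cortical composite
  evolves exactly as `DVR(t) = dvr0 (1 + rate/100 t)` and the early
  composite shows proportionally higher % change — as observed.
* **SUVR bias**: `SUVR - 1 = 1.30 (DVR - 1)` at baseline (30% proportional
  overestimation), with SUVR's specific-signal growth additionally inflated
  by 15% (`bias_slope_rate`), reproducing the separate proportional bias in
  rates.
* **Noise**: multiplicative Gaussian on the measured value,
  `obs = v (1 + eps)`, `eps ~ N(0, sigma)` independent per scan. The latent
  value cancels from the TRT ratio, so mean same-day TRT% is
  `2 sigma / sqrt(pi)` at every burden level and sigma is calibrated in
  closed form to the per-metric/ROI TRT targets (defaults 0.85% DVR / 1.61%
  SUVR cortical, 2.05% / 3.46% early — the CU-only values). An earlier
  variant applied the noise to the specific signal `v - 1`; that makes
  value-level TRT% scale with `|s|/(1+s)`, giving high-burden subjects
  roughly tenfold the slope noise of low-burden ones, which contradicts TRT
  studies spanning CU through AD and distorts the baseline-rate curve
  comparison. Region-level rows get `2 sigma` noise (as if the 4-member
  composite averaged independent region noise); composite rows are
  calibrated directly.
* **Scan times**: first scan at 0, last at the drawn span, interior times
  uniform on the middle 70% of the span — only the mean, SD and range of
  spans are published, so anything smoother would be invented precision.
* **TRT pairs**: a small TRT study is emulated as 4 CU (low-burden latent
  values) plus 7 impaired subjects (1 MCI, 6 AD; high-burden), one latent
  truth per subject with two independent noise draws per metric/ROI.

What the generator does **not** emulate: voxel-level data, scanner or
pipeline harmonization effects, within-subject correlation between metrics'
noise, dropout, non-linear (sigmoidal) long-horizon trajectories, or
cognitive decline. Passing tests therefore demonstrate the statistical
machinery under the cohort's published summary structure, not properties of
any real dataset.

## Association analyses

Bland-Altman comparisons treat DVR as the reference: the proportional bias
slope is the OLS slope of (SUVR − DVR) on DVR (the convention when a
reference standard exists; the slope against the pair mean is also reported).
Correlation is Spearman for baselines, Pearson for rates. The paired test is
t when Shapiro-Wilk on the differences does not reject at alpha = 0.05, else
Wilcoxon signed-rank, and the choice is reported. The baseline-rate shape
comparison fits linear, quadratic and natural cubic spline (boundary knots at
the data range, one interior knot at the median) by least squares with
Gaussian AIC `2k − 2 logL`; reported deltas are AIC(quadratic) −
AIC(competitor), negative favoring the quadratic. With a quadratic generating
truth the spline's margin is chance-scale (~chi-square with 1 df), so the
spline occasionally wins a seed — published margins of this comparison are
similarly razor-thin. Covariate models are OLS: baseline ~ age + sex + apoe4,
and rate ~ age + sex + apoe4 + baseline (a mixed-model refit adds little for
per-subject EB slopes); constant covariates are dropped with a warning.

## Pipeline and reproducibility

`run_pipeline` chains simulate → quantify → fit → TRT → associate → power,
writes CSV outputs plus a stats JSON, and records a manifest with the SHA-256
of the canonicalized configuration and the seed; identical config and seed
give byte-identical deterministic outputs. One seed drives every stochastic
stage through independent derived streams. Stage failures abort with the
stage named. Subject stratification in the pipeline uses the observed
first-session cortical SUVR converted to Centiloid (as an analysis of real
data would); ground-truth strata remain available for parameter-recovery
testing.

## Problem sizes used in tests

The test suite runs the full default cohort (n = 237) once, a 50-seed
repetition of the accumulator comparison, 10 Monte-Carlo power validations at
1e5 replicates each, and >= 1e4 simulated TRT pairs per calibration check —
sizes chosen so each check's sampling error sits well inside its assertion
tolerance.

## Known limitations

* The SUVR bias model is a fixed proportional map, not a kinetic consequence;
  the quantification layer reproduces the overshoot mechanistically, but the
  fast value-mode generator uses the affine shorthand.
* TRT noise is independent across metrics and ROIs; real SUVR and DVR errors
  from the same scan pair are correlated.
* Mixed models assume homoscedastic residuals; the generator's value-level
  noise satisfies this only approximately across burden levels.
* The Centiloid map and composite weights are configurable stand-ins, not
  site-validated conversions.
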