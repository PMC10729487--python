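# Methods

`adbrainage` implements a complete brain-age-gap (BAG) analysis for
autosomal dominant Alzheimer disease (ADAD) cohort data: calibration of
raw brain-predicted ages, multi-site harmonization, nonlinear trajectory
modelling over estimated years to symptom onset (EYO), divergence-point
estimation and comparison, and biomarker/cognition association and
mediation models. Because real ADAD cohort data are restricted-access,
the package ships a synthetic cohort generator with known ground truth;
every stage is validated by parameter recovery against that truth.

## Brain-age calibration

Predicted ages from machine-learning age models regress toward the
training mean ("regression dilution"): in healthy controls the slope of
predicted on chronological age is below one, which induces a spurious
negative age trend in BAG. We fit `raw ~ alpha + beta * age` by OLS in
non-carrier (NC) controls only, and correct every prediction as
`corrected = (raw - alpha) / beta`. An equivalent family of corrections
subtracts the fitted NC residual trend instead; both zero the NC age
trend, and we fix the rescaling form because it leaves a 1:1
corrected-vs-age relationship in controls. BAG is `corrected - age`
(positive = older-appearing). The correction is idempotent: refitting on
corrected values yields slope 1, intercept 0.

Model performance (Pearson r, MAE, RMSE, and R²) is always computed on
*uncorrected* predictions — correcting first would inflate apparent
accuracy. R² is defined against the identity line,
`1 - SS(pred - age) / SS(age - mean)`, not as r²; this is the convention
under which a correlation of 0.82 coexists with R² = 0.50, and it may be
negative. When per-slice CNN outputs are supplied (e.g. 80 axial slices
per scan), the participant-level prediction is their median (mean of the
two central values for even counts).

Test-retest reliability uses ICC(A,1): two-way model, single measurement,
absolute agreement, `(MSR - MSE) / (MSR + (k-1)MSE + (k/n)(MSC - MSE))`
with k = 2 and F-based confidence bounds. It is verified against an
independent ANOVA oracle and against `pingouin`.

## Site harmonization (ComBat)

Scanners and sites add non-biological location/scale variation. We use
the empirical-Bayes location/scale model of Johnson et al. (2007) adapted
to a single response: covariate effects (age, sex, education, group, EYO,
APOE ε4, mutation variant) are estimated jointly with batch indicators;
residuals are standardized by the pooled SD; per-batch locations get a
normal prior and squared scales an inverse-gamma prior, with
hyperparameters estimated *across batches* by method of moments
(classical ComBat estimates them across genomic features, which do not
exist here); the posterior estimates are solved by iterated conditional
means to a 1e-6 tolerance (max 200 iterations). Adjustment removes the
EB location, divides by the EB scale, and restores the covariate fit
exactly, so preserved-covariate coefficients are unchanged up to
estimation noise.

Choices: the batch variable is site; scanner differences are tested
pre/post but not separately harmonized (a sequential site-then-scanner
pass is available behind `sequential_scanner`). EB shrinkage means
harmonization is only approximately idempotent — a refit-and-reapply
pass moves values by order `delta/(n_b * tau^2)`, a few percent of the
data SD, not zero. Sites with fewer than 5 participants are excluded
from the analysis set (the usual eligibility rule for multi-site
harmonization; single-participant "batches" are not estimable). Batch
differences are checked with tie-corrected Kruskal-Wallis tests; the
all-values-equal degenerate case returns H = 0, p = 1.

## Trajectory GAMMs

The measure (BAG or another MRI-derived index) is modelled over EYO as

    y = b0 + b1*carrier + f_NC(eyo) + f_MC(eyo)
        + sex + education + APOEe4 + u_family + eps

with group-specific smooths, Gaussian errors, and a family random
intercept capturing the genetic/household clustering of carriers and
non-carrier relatives.

Each smooth is a cubic regression spline with k = 4 basis functions — a
natural cubic spline parameterized by its values at knots placed at
evenly spaced EYO quantiles, with the integrated-squared-second-derivative
penalty (null space = linear functions) and a sum-to-zero constraint per
group absorbed by reparameterization. The random intercept is expressed
as a ridge-penalized indicator block, so the whole model is one penalized
least-squares problem; smoothing parameters and the variance ratio are
selected by restricted maximum likelihood with sigma² profiled out. The
family block's cross-products are diagonal, so fits are solved through
the Schur complement on the small dense block — cost O(n·p²) in the
dense dimension only, which keeps 10,000-replicate bootstraps tractable.
The implementation reproduces `mgcv::gam(..., bs="cr", method="REML")`
predictions to ~1e-8 on shared knots (cross-checked in the test suite),
and the family LME path matches `statsmodels` MixedLM fixed effects and
variance components.

Smooth-term inference: EDF is the trace of the smoother sub-block
(bounded by [1, k]); the test statistic is a Wald quadratic form on the
smooth coefficients with a fractional-rank inverse of their Bayesian
covariance, referred to chi-square with EDF degrees of freedom. Its null
rejection rate is verified to sit inside the binomial envelope of 5%.

### Simultaneous bands and divergence

Group curves are evaluated at population-average covariates. For a grid
of EYO values, coefficient vectors are drawn from the posterior normal
N(beta, Vb); the critical multiplier m is the level-quantile of the
maximal standardized deviation over the grid, and the band is
`fit ± m·SE`. m always dominates the pointwise normal quantile (1.386 at
83.4%). Non-overlap of the two groups' simultaneous 83.4% bands is the
two-group comparison convention (approximates a test at alpha ≈ 0.05);
we use band non-overlap rather than a CI on the difference smooth to
match the overlapping-interval convention. The earliest divergence EYO
is the first grid point from which separation is sustained through the
grid maximum, suppressing isolated crossings. The default evaluation
grid covers the overlap of the two groups' inner 2.5–97.5% EYO quantile
ranges: beyond that, one group has essentially no data, standard errors
explode, and sustained separation could never be certified. The primary
grid step is 0.05 EYO (the bootstrap uses 0.25–0.5 with 200–500
posterior draws; the divergence point varies far more across resamples
than across grid refinement).

Whole-curve coverage of the 83.4% band is verified at 83.4% ± 4% over
500 replicates in a regime where the truth lies in the spline space and
the signal is well identified; penalization bias (truths outside the
model space, or smooths shrunk toward linearity) degrades simultaneous
coverage, a known property of posterior bands that do not propagate
smoothing-parameter uncertainty.

### Bootstrap comparison across measures

Participants are resampled with replacement, stratified by the
three-level group (family-level resampling is available behind
`resample="family"`); every measure is refit on the same resample with
knots and smoothing parameters fixed at their full-data estimates
(re-estimating lambda per replicate adds noise and an order of magnitude
of cost), random intercepts refit per replicate. Replicates with no
sustained divergence are censored at the grid maximum and counted; a
measure censored in more than half its replicates is flagged and its CI
reported one-sided. Pairwise p-values are
`2 · min(Pr(diff < 0), Pr(diff > 0))` over paired replicate differences,
which is calibrated (~5% false positives) for equal-truth measure pairs.

### Divergence-point estimator bias

The band-non-overlap estimator certifies the earliest EYO where the
groups *demonstrably* differ, which is intrinsically later than the true
onset when the divergence starts gradually. With the generator's
C¹ quadratic ramp (see below), the true group separation at 1.5 y after
onset is only ~0.3 y, while certification requires separation exceeding
the sum of both bands' half-widths (~3 y at n ≈ 450 under realistic
residual noise). The recovery test in the acceptance suite measures this
directly: at the default conditions the estimated divergence sits several
years after the true ramp onset, at any noise level a brain-age model
could plausibly achieve. Interpreting an estimated divergence EYO as the
biological onset of separation is therefore conservative by construction;
only the comparison *between* measures (which share the bias) is
calibrated.

## Group comparisons and associations

Group BAG differences use an omnibus Kruskal-Wallis test followed by
pairwise two-sided Wilcoxon rank-sum tests (exact enumeration for
combined n ≤ 20 without ties, otherwise the tie/continuity-corrected
normal approximation) with Benjamini-Hochberg FDR adjustment, plus the
classic mean-centered Levene test for variance homogeneity. Effect size
is the pooled-SD Cohen's d with a normal-approximation 95% CI
(`SE² = (n1+n2)/(n1·n2) + d²/(2(n1+n2-2))`).

Biomarker models are linear mixed models
`BAG ~ biomarker * group + sex + education + APOEe4 + (1|family)` fit by
the same REML engine; Wald t/F tests use df = n − total EDF and partial
eta² = F·df1/(F·df1 + df2) (a Wald-based definition; sums-of-squares
variants differ slightly in unbalanced designs). Significant
interactions are followed by within-group Pearson correlations. The
log-transform sensitivity refits the same model on natural-log biomarker
values, refusing non-positive inputs with the offending rows listed.
Asymptomatic-carrier CDR-SB correlations are not computed (near-zero
variance).

Mediation (biomarker → BAG → cognition) uses two nested linear models;
the indirect effect a·b gets a percentile CI from a non-parametric
participant bootstrap (family clustering intentionally ignored inside
the bootstrap, matching the standard method; a family option exists).
For nested OLS fits total = direct + indirect exactly. Labels: "none"
when the indirect CI covers 0; otherwise "partial" if the direct path is
significant at 0.05, else "full" (the sample direct effect is never
exactly zero, so significance is the operative criterion).

## Synthetic cohort generator

The generator emulates the structure of a multi-site ADAD observational
cohort with 179 NC / 183 asymptomatic / 74 symptomatic participants by
default and the corresponding per-group age, EYO, education, sex, APOE
and mutation-variant marginals. Ages and EYOs are drawn directly from
the per-group marginals and the onset age recorded as `age − eyo`
per participant; a single family-level onset cannot match both marginals
simultaneously, so onset bookkeeping varies within family (the family
random intercept, not a shared onset, carries the familial clustering).
Families have 1 + Poisson(mean−1) members mixing carriers and
non-carrier relatives, share a mutation variant, a site (hence scanner)
and a normal random intercept (SD 2 y). Sites add a normal shift
(SD 1.5 y by default — enough to make the pre-harmonization site test
borderline-significant at the default n, as in multi-site brain-age
data); scanners scale the noise log-normally (SD 0.1).

The carrier disease signal is a quadratic ramp in EYO,
`A·(eyo − d0)₊²` with onset d0 = −7 y, C¹ at onset, with A calibrated in
closed form so the mean ramp height over the symptomatic-stage EYO
distribution N(1.4, 5.7) equals 13.4 y. A quadratic is smooth enough for
a k = 4 spline to track; note it is unbounded, so late-stage carriers
(EYO > +10) receive very large values, which dominates within-group
variance in the symptomatic group. Sex (+3.15 y for males) and education
(−0.38 y per year) shift BAG in all groups. The uncorrected prediction
is `age + true_bag + family + site_shift + scanner_scale·noise` with
residual SD 6 y — chosen to match the printed NC accuracy (identity-line
R² of 0.50 at an age SD of 10.6 implies a ~7.4 y corrected residual) and
the symptomatic effect size (d = 1.72 for a 13.4 y shift implies a
pooled SD of ~7.8 y).

Biomarkers (amyloid PET SUVR, CSF Aβ42/40, CSF pTau/Aβ40, plasma
pTau-181, CSF and plasma NfL, cognitive composite, CDR-SB) are generated
within group as `mu_g + sd_g·(r_g·Z + sqrt(1-r_g²)·eps)` where Z is the
standardized *measured* biology deviation (true BAG + family + noise —
what survives harmonization). Targeting the measured signal makes the
observed biomarker-BAG correlations land on the configured magnitudes
(e.g. 0.53 for plasma pTau in symptomatic carriers); targeting the
latent truth instead would attenuate them by ~30%. Group-level scales
are plausible assay values and can be overridden per spec. Retest pairs
are constructed as `v2 = m + rho(v1−m) + sqrt(1−rho²)·s·eta`, an
exchangeable equal-variance pair whose population ICC(A,1) equals the
target (0.94 by default). CDR is 0 outside the symptomatic group and
0.5/1/2 with the cohort's observed proportions within it.

What the generator does *not* emulate: longitudinal within-person
trajectories (beyond the single retest pair), missing-data mechanisms,
non-Gaussian biomarker skew (the log-sensitivity tests construct skewed
data explicitly), realistic within-variant onset-age distributions, and
any image-level structure. Passing recovery tests therefore demonstrates
the statistical machinery, not robustness to every feature of real data.

### Simulation designs used in the acceptance suite

Scenario parameters are chosen to isolate the property under test:

- Band coverage: truth inside the spline space, n = 150, sigma = 3 —
  the regime where posterior-simulation bands are advertised to attain
  nominal whole-curve coverage.
- Interaction calibration/power: balanced groups (134/133/133 at
  n = 400), equal within-group biomarker SDs (slopes are only comparable
  on a common x scale), correlation targets (0.5, 0.2, 0) or (0, 0, 0),
  and the divergence ramp switched off so the response is homoscedastic —
  the ramp is an orthogonal variance source that otherwise dominates the
  pooled residual.
- Bootstrap comparison: two extra measures with known divergence truths
  (−7/−7 and −7/−3) sharing the cohort's EYO/family structure at reduced
  measure noise (3 y), n = 600, n_boot = 500.

## Numerical choices

- REML optimization: bounded scalar search (1 free parameter) or
  Nelder-Mead (2–3), on log-lambda in [−10, 16]; Cholesky with a
  jittered fallback; EB ComBat tolerance 1e-6, max 200 iterations.
- Degenerate inputs: all-equal values give H = 0/p = 1 (rank tests) and
  W = 0/p = 1 (Levene); zero-variance retest tables give ICC 1; constant
  regressors and rank-deficient designs are refused with named errors.
- Determinism: every stochastic stage consumes a `numpy` Generator
  seeded from the stage seed, which the pipeline derives from the single
  config seed and records in the run manifest; reruns are byte-identical.
- Bootstrap: posterior-draw seeds are shared across measures within a
  replicate so pairwise comparisons are paired all the way down.

## Known limitations

- The divergence-point estimator's conservatism (see above) is the
  dominant caveat when reading absolute divergence EYOs.
- Single-variable ComBat estimates EB hyperparameters across batches;
  with very few batches the priors are weak and shrinkage is minimal.
- The smooth-term p-value and the LME Wald F are approximations whose
  calibration is verified empirically at the package's default scales,
  not theorems.
- partial eta² uses the Wald-F definition; it is reported for
  comparability, not as an exact variance decomposition.
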