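# Methods

## Model and procedure

The pipeline operates on a subject × variable cohort table: 14 bilateral
subcortical volumes (mm³), total WMH volume (mL), demographic and vascular
covariates, and six cognition scores. Three statistical components are
chained:

**SSM covariance pattern.** Volumes are natural-log transformed and
double-centered (subject means first, then region means; the two projections
commute, so the order is immaterial and is tested as such). The "modified
PCA" of the SSM is realized as the SVD of this residual matrix — that is the
operational content of the centering-plus-PCA recipe, and no further
modification is applied. Loadings are unit-norm with all magnitude
information in scores and eigenvalues, which keeps bootstrap sign alignment
and cosine comparisons well defined. Because double centering removes one
rank in each direction, min(n−1, p−1) components are retained. The sign of
each loading column is fixed by making its largest-magnitude element
positive.

**BIC component selection.** Candidate models are the nested first-k sets,
k = 1..k_max (default k_max = min(n−2, p−1, 10)); an all-subsets search is
available behind `search="exhaustive"` for sensitivity analysis, but nested
search is the default because the pattern is defined as a combination of
*leading* components. BIC uses the Gaussian form n·ln(RSS/n) + (k+1)·ln n,
counting the intercept but not σ²; constant offsets are identical across k
and cannot change the argmin, so this choice is inconsequential for
selection. Ties within 1e-9 resolve to smaller k (parsimony). RSS is floored
at TSS·1e-24 so that an exactly fitting model does not keep "improving"
through rounding noise as parameters are added. The combined weight vector
is sign-anchored so that expression correlates positively with log WMH,
i.e. higher expression = more WMH-like topography.

**Expression scoring.** A trained pattern stores the training region means
and the training mean/SD of the raw projection. New subjects are scored by
row-centering their log-volume profile, removing the stored region means,
projecting onto the weights and standardizing with the training constants.
On the training cohort this reproduces the regression-route expression to
numerical precision; subject-mean centering makes scores invariant to global
volume scaling (the testable form of the SSM's global-scaling rationale).
TIV is deliberately *not* regressed out of the volumes — subject-mean
centering is the pipeline's size adjustment, and TIV enters only as a
mediation covariate.

**Bootstrap CIs on weights.** The resampling unit is always the subject.
Within each replicate the full derivation is rerun with k *fixed* at the
point-estimate selection: reselecting k per replicate would mix
model-selection variability into the weight CIs (a reselect-per-replicate
mode exists behind a flag). Replicates are unit-normalized and sign-aligned
by dot product with the point estimate; replicates orthogonal to it
(|dot| < 1e-12) or with rank-deficient regressions are discarded and
counted, with a warning if more than 1% fail. Intervals are percentile (not
BCa), the same convention the mediation models use. The replicate
computation is vectorized (batched eigendecomposition of the region
covariance, equivalent to the per-replicate SVD; equality with an explicit
single-replicate rerun is covered by a test.)

Percentile CIs on a sign-aligned unit-norm direction are *conservative*
under a global null: when no pattern exists, replicate directions rotate
broadly, intervals are wide, and the per-region false-positive rate is far
below the nominal 5% (measured ≈0.5–1% on null cohorts). The procedure's
value is its sensitivity under a real pattern, not exact null calibration.

**Mediation.** All paths are OLS on listwise-complete rows. Predictor,
mediators and outcome are z-scored; continuous covariates are z-scored;
binary covariates stay 0/1 (they only absorb variance, and their own
coefficients are not reported as effects — for the effects of interest the
choice is inconsequential). Indirect effects are products of standardized
paths; the in-sample identity c_total = c' + Σ indirect holds exactly
because every equation is OLS with the same covariate set and sample. The
bootstrap re-standardizes within each replicate, treating standardization as
part of the estimator (the conservative choice), and reports the replicate
SD as the bootstrap SE plus percentile CIs. Per-path p-values come from OLS
t-tests. Two-tailed α = 0.05 throughout, with no multiplicity correction
across the six outcome models — a deliberate mirroring of the analysis
design, and a caveat for interpretation.

The simple models use the TMT-A-residualized TMT-B score (computed from
*raw* scores, then z-scored) as the shifting outcome; the serial models use
log TMT-B time directly, with processing speed handled by the mediator
chain. The reversed-order comparison model swaps the second mediator and the
outcome (pattern → GPT → TMT-A) to test the directional specificity of the
speed pathway.

## Synthetic cohort generator

The generator emulates the study conditions of a healthy-aging cohort of
n = 178: age 69.77 (10.22) years, WMH 6.68 (10.28) mL (log-normal,
moment-matched — the reported mean < SD indicates right skew), and the
reported marginal moments for education, BMI, VO₂max, depression ratings
(negative-binomial, moment-matched), scan–test interval (gamma), binary risk
factors, and all six cognition scores. One TMT-B and one GPT value are set
missing by default (n = 177 complete), exercising listwise deletion.

Structure is planted on standardized latent scales:

- latent pattern score `s = 0.492·z(age) + noise` (unit variance);
- `ln volumes = baseline + global size factor + s·w + N(0, σ²)` with `w`
  the mean-removed, unit-norm topography (−1 putamen L/R, −0.7 accumbens L,
  +0.8 caudate L/R before normalization — signs from the described
  topography, magnitudes free choices);
- `z(ln WMH) = 0.62·s + noise`, then affinely mapped to the target
  log-normal marginal (0.62 ≈ √0.389, the reported variance explained);
- `z(log TMT-A) = 0.234·s + 0.262·z(age) + noise`;
- each downstream outcome `= d·z(log TMT-A) + c·z(age) + noise`, with the
  direct age couplings c taken from the reported standardized direct
  effects and the speed couplings d set so the implied serial indirect
  effects (0.492·0.234·d) match the reported ones (memory −0.278, shifting
  +0.539, working memory −0.287, inhibition −0.347, fine motor +0.182).

Timed scores are generated on the log scale and exponentiated so the
pipeline's own log transforms are exercised. All disturbances are scaled so
every structural variable has unit population variance, making the planted
coefficients exactly the completely standardized paths that the mediation
stage estimates. Covariates are generated independent of the pattern (the
study reports no covariate–pattern couplings to emulate; WMH–TIV and
WMH–sex covariances are likewise unreported and left at zero). The latent
score is returned as a non-analytic ground-truth column.

`noise_sd_regions` defaults to 0.4. The recipe pins var(s) = 1 and |w| = 1,
so the absolute log-volume scale is conventional and only the
signal-to-noise ratio is a real degree of freedom; 0.4 places weight
inference at n = 178 in the regime the reported bootstrap figure shows —
core topography regions significant, near-zero regions mostly not. With
much smaller noise every region, including those with weights ≈0.04 induced
by mean removal, is flagged, which no real volumetric study shows.

The null generator removes the pattern from the volumes, decouples WMH and
processing speed from `s`, and leaves everything else intact; it is used for
type-I-error calibration.

**What the generator does not emulate:** measurement error specific to
segmentation pipelines, non-Gaussian volume residuals, covariate–pattern
confounding, spatial correlation between neighboring structures beyond the
single planted component, floor/ceiling effects in cognitive scores, and
longitudinal structure. Passing recovery tests therefore demonstrates the
estimator chain is correct and calibrated under the planted model, not that
the scientific conclusions transfer to any particular real cohort.

## Numerical choices and degenerate inputs

- Centering identities and reconstructions are asserted to 1e-10; SVD/eigh
  agreement and score orthogonality to 1e-8; OLS-oracle path equality to
  1e-10.
- Nonpositive volumes, WMH or timed scores raise domain errors naming the
  subject and column; missing region volumes may not be imputed and raise.
- If the TMT-B-on-TMT-A residual SD is numerically zero (exact
  proportionality), residuals are set to zero rather than amplifying
  rounding noise through standardization.
- Collinear mediation designs (e.g. duplicated mediators) raise with the
  offending column list; constant columns cannot be standardized and raise.
- Bootstrap replicates with singular normal equations are discarded and
  counted (`n_failed`), never silently imputed.

## Problem sizes used in the test suite

Monte-Carlo checks run at the sizes the properties are stated at: pattern
recovery over 100 cohorts of n = 1000; bootstrap calibration over 100
cohorts of n = 500 with 1000 replicates; mediation CI coverage over 500
simulations of n = 500 with 1000 replicates; the serial-direction structure
over 200 study-scale cohorts (n = 178). The analysis drivers default to
10,000 bootstrap iterations (the reported convention); tests and the
acceptance script use 1000–2000, which is ample for 95% percentile
endpoints at the tolerances asserted.

## Known limitations

- The percentile bootstrap for an indirect effect is mildly anticonservative
  when exactly one path is null (measured ≈91% coverage at the 95% nominal
  level) — a documented property of the method, not an implementation
  artifact.
- Under a global null the weight CIs are strongly conservative (see above);
  users wanting calibrated per-region nulls should use permutation tests,
  which are out of scope.
- Nested-first-k selection cannot pick a non-leading component alone;
  `search="exhaustive"` exists for that sensitivity check.
- Mediation models are associational path models on cross-sectional data;
  nothing here supports causal claims.
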