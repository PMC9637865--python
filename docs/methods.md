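# Methods

This note documents the statistical model, the synthetic-data conditions,
the numerical choices, and the limitations of the `normdev` pipeline.

## Normative model

Each global feature is modeled by Bayesian linear regression (BLR) with a
Gaussian weight prior of precision α and Gaussian noise of precision β. The
design concatenates an intercept, raw age (years), a {0,1} sex code, and a
clamped cubic B-spline expansion of age with three interior knots evenly
spaced between the observed minimum and maximum training age (boundary
knots repeated degree+1 times), giving 7 basis columns and 10 design
columns in total. The clamped spline span already contains constants and
affine functions of age, so the design is deliberately rank-deficient
(numerical rank 8); the α-ridge prior regularizes it, and all posterior
computations go through the regularized precision matrix
A = αI + βΦᵀΦ — no pseudo-inverse is ever formed. Keeping the redundant
intercept/age columns mirrors the common toolkit convention of
concatenating covariates with the basis; the fitted mean function is
unaffected, only the (unreported) individual weights are.

Hyperparameters maximize the log evidence

log p(y|α,β) = d/2·log α + n/2·log β − n/2·log 2π − ½·log|A| − β/2·‖y−Φm‖² − α/2·mᵀm

by Powell's method over (log α, log β), starting at (0, log(1/var(y))),
with up to three jittered restarts on non-finite results. The evidence is
validated in tests against the dense N(0, ΦΦᵀ/α + I/β) log-density, and the
α→0 limit against least squares.

The likelihood is homoskedastic Gaussian with no warping. A monotone
warped-likelihood hook was considered, but the features modeled here are
near-Gaussian by construction and the identity likelihood is the
appropriate default; non-Gaussian warp families are out of scope.

Deviation scores are out-of-fold Z-statistics under k = 10-fold
cross-validation: folds are a seeded uniform shuffle followed by a
contiguous split (no stratification); the spline basis is rebuilt on each
training fold's age range, and test ages falling outside it are clamped to
the boundary with a logged warning (clamping only occurs inside
cross-validation; direct basis evaluation outside the boundary is an
error). The predictive variance includes the weight-posterior term, so
z = (y − φᵀm)/sqrt(1/β + φᵀSφ). Out-of-sample metrics use population (1/n)
variances: explained variance 1 − var(resid)/var(y), SMSE mse/var(y), MSLL
relative to each training fold's mean/variance Gaussian, and Pearson ρ of
predicted vs observed (reported as 0 with a degeneracy flag when the
predictions are constant).

## Behavioral decomposition

The cognitive general factor is the first principal component of the 14
column-standardized test scores, with scores re-standardized and the sign
chosen so the mean loading is positive. The factor score is then passed
through exactly the same normative model as a brain feature, yielding
COG_dev.

The 129 ordinal items are decomposed by a stability-resampled FastICA
(logcosh contrast, unit-variance whitening, tol 1e−4, max 500 iterations).
The default n_runs = 20 runs use different seeded initializations; runs
after the first also bootstrap-resample subjects, because refitting the
same sample only probes optimizer reproducibility — on pure Gaussian data
FastICA converges to the same empirical-kurtosis maxima from any start, and
only resampling reveals that those maxima are not population features.
Every run's unmixing is applied to the full sample, the pooled source
estimates are clustered by average-linkage agglomeration on 1 − |corr|
distance into 7 clusters, and each cluster's centrotype (the member most
similar to the rest of its cluster) is kept. Per-component stability is the
mean within-cluster minus mean between-cluster similarity; a mean below 0.5
triggers a logged warning that no reproducible non-Gaussian structure was
found. Subject weights are the least-squares projection of the
standardized data on the representative mixing matrix (the alternative —
reporting raw run-specific source estimates — would not be comparable
across components from different runs). Components are sign-oriented so
the sum of each component's ten largest-|loading| item loadings is positive
(higher weight = more symptoms; the orientation is idempotent) and ordered
by explained item variance. The general-psychopathology proxy is the
row-wise arithmetic mean of the seven weights.

## Association stage

Pairwise Pearson correlations (with two-sided t-test p-values and
0.05/0.01/0.001 star markers) summarize the convergence of the seven
deviation scores. Each (brain deviation × behavioral score) pair — 6
features × (7 components + general + COG_dev) = 54 models — is a Gaussian
linear regression of the deviation Z on standardized age, the raw {0,1}
sex code, and the standardized behavioral score, fit one predictor at a
time to match per-domain reporting. "Standardized" means direct
z-scoring on the analysis sample; no residualization against other
variables is applied.

Priors: N(0, 1) on the standardized domain coefficient (a proper prior is
required for the Savage–Dickey ratio; unit scale is the natural default for
a standardized coefficient and is configurable), diffuse N(0, 10) on
intercept/age/sex, and half-Student-t(3, 0, 2.5) on the residual SD. The
posterior is computed conditional on σ in closed form and σ is marginalized
numerically over a 161-point geometric grid spanning [σ̂/4, 4σ̂] around the
OLS residual scale; posterior summaries, densities and credible intervals
come from the resulting Gaussian mixture, and exact independent draws from
the same mixture provide the sampling cross-check. BF01 is the posterior
density of the domain coefficient at zero divided by the prior density at
zero; the sampling-based estimate uses a Gaussian KDE (Silverman-type
bandwidth) and requires at least 1000 draws — note the pointwise KDE has a
relative Monte Carlo SD of roughly 5 % at 8000 draws, so tight analytic
comparisons should use several tens of thousands. With no data the
posterior reduces to the prior and BF01 = 1 exactly. Evidence labels follow
the conventional bands (alternative side [lower, upper): <0.01 extreme,
0.01–0.03 very strong, 0.03–0.1 strong, 0.1–0.3 moderate, 0.3–1 anecdotal;
null side (lower, upper]: 1–3 anecdotal, 3–10 moderate, 10–30 strong,
30–100 very strong, >100 extreme; BF01 = 1 is evidence in either
direction). No multiple-testing adjustment is applied across the grid; the
run report flags this explicitly.

## Synthetic cohort generator

The generator produces the structure the analysis assumes, with every
latent quantity returned for ground-truth checks. Defaults (the study
conditions): n = 1280 subjects, ages uniform on 8–22 years, sex
Bernoulli(0.5). Feature trajectories are low-order polynomials in scaled
age chosen to match the developmental literature qualitatively — FA rises
and saturates (0.40 → ~0.46), MD/RD/L1 (units 10⁻³ mm²/s) decline, mean
cortical thickness (mm) thins monotonically (~2.85 → ~2.60), total surface
area follows an inverted U peaking in early adolescence, and the cognitive
latent rises with age. Sex offsets are small except for surface area.
Deviation scales and measurement-noise SDs are set so that age and sex
explain roughly 30–40 % of each feature's variance, the regime in which
global developmental features typically sit.

Per-subject deviations are unit-variance latents with a fixed 7×7 target
correlation (FA–RD −0.88, FA–MD −0.60, MD–L1 0.78, RD–L1 0.45, CT nearly
independent of the diffusion features, SA moderately tied to FA and
cognition; positive-definiteness is checked at construction), scaled into
feature units. By default the latent draws are empirically
moment-matched — the sample is whitened and recolored so its correlation
equals the target exactly, as in `MASS::mvrnorm(empirical = TRUE)` — so the
cohort carries the specified deviation structure rather than a Monte Carlo
approximation of it; `match_moments=False` gives plain i.i.d. MVN
sampling. Deviations are i.i.d. across age (no age-dependent variance),
matching the evenly-distributed-variance regime the analysis assumes.

Questionnaire items arise from 7 latent domain scores through a
simple-structure loading matrix (item i loads 0.6/0.7/0.8 on domain
i mod 7) with the remaining variance as independent Gaussian noise, then
thresholded at (0.5, 1.2, 2.0) on the latent scale into 0–3 ordinal levels,
giving the right-skewed, mostly-zero distributions typical of symptom
screens. Item-level distributions of real screening interviews are not
publicly tabulated; the thresholds are configurable placeholders. The 14
cognitive tests load 0.7 on the latent cognitive trajectory with
independent noise.

Injected effects are specified as standardized coefficients β (deviation-Z
units per SD of domain score). Because the observed deviation
Z ≈ (scale·u + noise)/sqrt(scale² + noise²) attenuates the latent
correlation by scale/sqrt(scale² + noise²), the generator inflates the
latent domain-deviation weight by the inverse of that factor (for the
cognitive feature, additionally by an approximate factor-score reliability
term ν/(λ̄√p) for the battery's extraction error), so the recoverable
coefficient equals β. Effects on "general" solve
7c/sqrt(7 + 42c²) = target for the common per-domain weight c. Effects
jointly implying domain variance above 1 are rejected.

A single seed is expanded through `numpy.random.SeedSequence` into named
substreams (demographics, deviations, domains, items, cognition, noise in
the generator; simulate/normative/decompose/associate in the pipeline), so
identical configuration gives byte-identical output and individual stages
can be rerun reproducibly.

### What the generator does not emulate

Real cohorts have non-uniform age distributions, site and scanner effects,
heteroskedastic and age-dependent deviation variance, item-level
missingness, QC-driven attrition correlated with age and symptoms, and
cross-loading questionnaire structure. Passing tests on this generator
therefore demonstrate that the estimation machinery is correct and
calibrated under the model's own assumptions — not that those assumptions
hold in any particular real dataset.

## Problem sizes used in validation

The test suite validates calibration at n = 2000 (10-fold CV; out-of-fold
Z mean/SD and Kolmogorov–Smirnov distance to N(0,1)), parameter recovery
over 200 replicates of n = 2000 with an injected β = −0.10 (coverage and
bias), Bayes-factor behavior over 100 replicates of n = 1000, ICA recovery
on 4 Laplacian sources at n = 5000, and effect ranking over 50 replicates
of n = 2000 through the full ICA pipeline. The acceptance script runs the
complete pipeline at the default n = 1280 and a 50-replicate coverage
experiment. These sizes put Monte Carlo error comfortably inside each
check's tolerance while the whole suite runs in a few minutes on one core.

## Known limitations

- Single-site, cross-sectional, homoskedastic model: no hierarchical
  site effects, warped likelihoods, or longitudinal structure.
- The ICA subject weights use the projection convention; if the original
  decomposition of a target dataset used mixing weights directly, absolute
  scales will differ (correlations with external variables will not).
- The σ-grid marginalization assumes the residual SD lies within a factor
  of 4 of the OLS estimate — safe for n in the hundreds and beyond, not
  for tiny samples.
- Component labels IC1..IC7 are ordered by explained variance and carry no
  intrinsic semantic meaning; matching to named symptom domains requires
  external information (in tests, the generator's ground truth).
- The cognitive attenuation correction for injected COG effects is
  approximate (mean-score reliability), so injected cognitive effects are
  recovered with a small residual bias, unlike brain-feature effects.
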