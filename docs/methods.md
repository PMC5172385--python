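# Methods

This note documents the statistical models implemented in `dediffwm`, the
estimators behind them, the synthetic cohort the package uses to exercise
and validate every stage, and the numerical and design choices a maintainer
should know about.

## The scientific setting

Tract-averaged diffusion-MRI phenotypes (FA, MD, the NODDI indices ICVF,
ISOVF and OD, and optionally axial/radial diffusivity and mode of
anisotropy) summarize white-matter microstructure in 27 named pathways — 12
bilateral pairs and 3 midline structures, giving 27 *tract entries*.  In a
middle-aged and older cohort, each measure covaries positively across
tracts: a single general factor (gFA, gMD, ...) captures a substantial
share of the variance.  The package's central question is whether that
shared variance *grows* with age — de-differentiation — and its central
model is a factor model in which age moderates the factor structure
itself.

## Models

### Per-tract regression (`tract_effects`)

Each tract entry's measure is regressed on age, age², sex, age×sex and —
for bilateral tracts, whose left/right rows are stacked — a hemisphere
indicator.  The outcome and age are z-scored so coefficients are on the
outcome-SD scale; sex and hemisphere stay 0/1 (female = 0, left = 0).  The
quadratic term enters orthogonalized against [1, age] and its coefficient
is reported back on the raw-polynomial scale; the quadratic form is
reported only when the nested F-test improves on the linear fit at
p < 0.05.  Within a model, effects are flagged at p < 0.001.  Stacked
hemisphere rows reuse subjects; the default is plain OLS, with optional
cluster-robust (by subject) standard errors.

Dependent-correlation contrasts (is measure A's age association stronger
than measure B's, on the same people?) use Williams's t for two dependent
correlations sharing one variable, with df = n − 3.  The power utility
inverts the power function of the bivariate correlation test (exact
noncentral-t form by default; Fisher-z available) to report the minimal
detectable standardized association at given n, α and power, rounded to 3
decimals.

### One-factor measurement model (`factors`)

For each measure, the 22 core entries (the catalog minus the five
weak-loading entries: middle cerebellar peduncle, both medial lemnisci,
both parahippocampal cingula) load on one general factor:

    y[t] = v[t] + a1[t]·age + a2[t]·age² + a3[t]·sex + l1[t]·g + e[t]

with Var(g | covariates) = 1 for identification, Var(e[t]) = l2[t]², and
optional residual covariances between specific entry pairs.  age² paths
are included for every measure except FA.  Estimation is in two profiled
stages: per-entry least squares for the mean structure — exact joint ML
here, because every indicator shares the same design, so OLS equals GLS —
followed by maximum likelihood of the covariance structure
Σ = Λ Λ' + Ψ + R against the residual covariance, minimized with analytic
gradients (L-BFGS).  Standard errors come from the observed information
(finite-difference Hessian of the analytic gradient).  Missing cells are
handled by full-information likelihood over each subject's observed
entries (no residual pairs on that path; listwise deletion otherwise).

*Pruning*: entries with |standardized loading| < 0.3 are flagged for
removal.  *Residual covariances*: greedy forward addition ranked by a
score (modification) statistic — the squared likelihood gradient for the
absent covariance over its curvature — with bilateral homologues winning
ties, each addition confirmed by a likelihood-ratio test at p < 0.001, at
most 10 pairs, with the full addition path recorded.  *Factor scores*: the
regression method (posterior mean λ'Σ⁻¹e; Bartlett available).  By default
all covariate contributions are residualized out; when scores feed later
*age* analyses (mediation, age prediction), the age contributions are kept
in the indicators (`keep=("age_z", "age_z2")`) so the scores retain the
factor's age-related variance — a fully residualized score is orthogonal
to age by construction and would make those analyses vacuous.

*Pathway comparison*: the age effect is modelled as common (age → factor
only, tract age paths constrained to γ·l1[t]), independent (free age path
per tract, none on the factor), or common+independent (common plus
forward-selected tract-specific paths; age and age² paths always enter
together, selection by likelihood-ratio improvement at p < 0.05, candidates
ranked by the mean-structure score).  All three are fitted by ML on the
sufficient moments; AIC, BIC and χ² difference tests are reported and the
package never collapses the AIC/BIC verdicts into a single winner.

*Thalamic-radiation composite (gTR)*: the first unrotated principal
component of the six thalamic-radiation entries (anterior, superior,
posterior × hemisphere), sign-aligned so higher scores mean higher tract
values; returned standardized with the eigenvalue reported separately.

### Age-moderated factor model (`dediff`)

The de-differentiation model multiplies both loading terms by linear
functions of centered age:

    y[t]_i = v[t] + a1[t]·age_i + a2[t]·age_i² + a3[t]·sex_i
             + l1[t]·(1 + l1m·age_c_i)·g_i
             + l2[t]·(1 + l2m·age_c_i)·u[t]_i

so moderation is proportional to each tract's own loading.  In the
*invariant* variant l1m and l2m are two scalars shared by all 22 entries;
in the *tract-specific* variant they are per-entry (44 interaction
parameters).  The implied covariance for subject i is
Σ_i = Λ_i Λ_i' + Ψ_i + R with Λ_i[t] = l1[t](1 + l1m·age_c_i) and unique
SD l2[t](1 + l2m·age_c_i); R (from the unmoderated fit) is *not*
moderated.

Estimation is again two-stage: OLS residualization of the mean, then the
per-subject Gaussian likelihood over the covariance parameters.  For a
normal model the mean and covariance blocks of the information matrix are
orthogonal, so profiling the mean costs nothing asymptotically for the
moderation parameters and their standard errors.  Without residual pairs,
Σ_i is a rank-one update of a diagonal, and the likelihood and its
analytic gradient are evaluated with the Sherman–Morrison identity in
O(n·p) per call (the observation mask makes this path full-information);
with pairs, a low-rank Woodbury evaluation (rank 1 + 2·#pairs) is used
with numerical gradients.  Age enters the moderation in decades internally
for optimizer conditioning; all reported slopes are per year.

Communality — the proportion of a tract's conditional variance explained
by the factor — is

    h[t](a) = s/(s+u),  s = (l1[t](1 + l1m·a_c))²,  u = (l2[t](1 + l2m·a_c))²,

computed with delta-method SEs at the 5-year anchor ages 45, 50, ..., 75
and interpolated to a dense grid with a natural cubic spline through the
anchors (the curve reproduces the anchors exactly; a single least-squares
cubic is available).  Confidence bands propagate the anchor SEs through
the interpolant — the SE construction for non-anchor ages is a package
choice and is labelled as such in the outputs.  The headline summary is
the mean-communality change from 45 to 75 in percentage points, with a
delta-method SE.

*Local structural equation modelling (LOSEM)* gives a non-parametric
check: at each of 300 equally spaced ages in [45, 75] (tests and the
acceptance script use a 30-target smoke grid), subjects are weighted by a
Gaussian kernel in age (default bandwidth 2 years; 1–3 are sensible
sensitivity values), indicators are residualized by weighted least
squares, and an unmoderated one-factor model is fitted to the weighted
covariance with the kernel's effective sample size (Σw, kernel height 1 at
the target).  Targets with effective n below a floor (default 50) are
flagged and skipped.  Kernel bias makes the edges untrustworthy; interior
agreement with the parametric trajectory is the meaningful comparison.

### Mediation and age prediction (`mediation`)

The age → gFA association is decomposed through the two NODDI factors
(gICVF, gOD) as covarying mediators in a linear path model on standardized
variables.  In this just-identified linear system the decomposition
c = c' + Σ a_j·b_j holds exactly in-sample (enforced to 1e-8).  Indirect
effects get percentile-bootstrap CIs (default 2,000 seeded resamples) and
delta-method SEs; proportion mediated (c − c')/c is flagged unstable when
|c| is below a configurable floor (default 0.05).

Age prediction screens ten collinear candidates (five diffusion general
factors, five head-size-corrected volumetrics) by bootstrap stability
selection: the sample is split into equal train/test halves; on each of
1,000 bootstrap resamples of the train half an elastic net (mixing 0.5)
with penalty chosen by internal 10-fold cross-validation records its
nonzero coefficients; predictors included in > 60% of resamples are
confirmed by ordinary multiple regression in both halves (standardized β,
R², VIFs).  The penalty uses the one-standard-error parsimony rule on the
CV curve by default: with the CV-minimum penalty, pure-noise predictors
enter well over 60% of resamples and stability selection loses its
meaning; the 1-SE rule is the conventional fix ("min" remains available,
as does fixing the penalty once per split instead of per resample).

## The synthetic cohort

The generator (`cohort`) produces tract values from the moderated factor
model above, with known ground truth, so every estimator can be tested for
parameter recovery.  Ages follow a six-group mixture (group weights
290/505/559/800/876/483 over ~5-year bins spanning 44.64–77.12 years;
uniform optional); age is centered at 60 and scaled by 7.5 years
throughout.  Each measure's general factor has unit variance conditional
on age and carries an age path in that metric; the FA factor is generated
through the ICVF and OD factors with a direct age path, so the generating
mediated proportion is known in closed form.  Volumetrics are linear in
age and the factors with independent noise, scaled to unit variance.
Exclusion flags are assigned disjointly with fixed counts
(567/1,314/59/2 out of 5,455 raw) so the staged cascade reproducibly
leaves 3,513; Bernoulli-rate flags and MCAR missingness are options.
Per-measure defaults are calibrated so a one-factor fit explains roughly
41% of FA variance and 68% of ICVF variance, with loading-moderation
slopes of 0.008/yr (FA), 0.012 (MD), 0.006 (ICVF), 0.009 (ISOVF) and 0
(OD), and the five weak entries at loading 0.15.

What the generator does *not* emulate: non-normal tails, scanner or site
artefacts, informative missingness, spatially correlated measurement
error across neighbouring tracts beyond the explicit residual pairs, and
any longitudinal structure.  Passing recovery tests therefore show that
the estimators are correct under the model's own assumptions at realistic
n — not that real acquisitions satisfy those assumptions.

A note on its conventions: because each factor has unit variance
*conditional on age*, the closed-form communality
s/(s+u) is exact ground truth for the fitted models' communality, and
factor-score age associations in the generator run somewhat above the
per-tract ones (score shrinkage and tract-specific age paths both push the
score-age correlation up); the generator is calibrated to variance shares,
not to score-level age correlations.

## Numerical choices

- Optimizer: L-BFGS-B, analytic gradients on both likelihood forms,
  `ftol` 1e-13, gradient tolerance 1e-7.  Infeasible trial points (a
  moderated unique SD crossing zero inside the age range, or a non-PD Σ)
  return a large finite value so the line search can backtrack.
- Moderated fits start from the nested unmoderated solution (one warm
  start by default; random restarts via `n_restarts` — the warm start sits
  in the attraction basin, and convergence failures raise rather than
  returning silently).
- Identification: factor variance 1; the loading vector's sign is fixed by
  making its sum positive.  Unique SDs are estimated unsigned; a unique
  variance collapsing below 1e-4 of the indicator variance raises a
  Heywood-case error naming the entry.
- Degenerate inputs: rank-deficient regression designs raise with the
  collinear columns named; pairwise correlation matrices that are not PSD
  are projected to the nearest PSD matrix with a warning; age bins with
  n < 3 are omitted, n < 10 warned.
- The exclusion cascade is strictly ordered; a subject flagged at several
  stages is counted at the earliest.

## Problem sizes used in the test suite and acceptance script

Replicate-based checks run at the cohort scale the estimators target
(n = 3,500, 22 tracts) with smoke-scale replicate counts: 10 recovery
cohorts and 25 null cohorts for the moderated model, 20 cohorts for the
communality curve, a 30-target LOSEM grid, 50 mediation replicates at
2,000 bootstraps, 20 elastic-net runs at 200 bootstraps, and 20,000
trivariate draws for the Williams-t calibration.  Binomial acceptance
bounds are set to match those counts.  `scripts/acceptance.py` runs the
full pipeline once on the default 5,455 → 3,513 cohort.

## Known limitations

- The moderated model's mean structure is estimated by OLS rather than
  subject-weighted GLS; with strong moderation this is consistent but not
  fully efficient for the mean paths (the covariance parameters are
  unaffected).
- FIML is available only for the diagonal + rank-one covariance structure;
  residual pairs plus missing data fall back to listwise deletion.
- The Woodbury pairs path checks positive-definiteness through determinant
  signs and quadratic-form positivity, which in principle can miss a
  non-PD Σ far from the solution; residual covariances are held fixed at
  values from a PD base fit, where this cannot occur.
- Tract-specific moderation with 44 interaction parameters is estimable at
  n ≈ 3,500 but individual Wald tests are conservative for small slopes;
  the likelihood-ratio variant is provided.
- No multi-factor or bifactor structures, no longitudinal modelling.
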