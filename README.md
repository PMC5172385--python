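# dediffwm

Age de-differentiation of brain white-matter microstructure: a tested,
reusable implementation of the tract-level and latent-variable analyses
used to study ageing in large single-scanner diffusion-MRI cohorts, built
around a synthetic cohort generator with known ground truth.

## Who this is for

Researchers analysing tract-averaged diffusion phenotypes (FA, MD, NODDI
indices) across many white-matter pathways in ageing cohorts, who need:
per-tract age/sex/hemisphere models; general-factor (one-factor) models of
cross-tract covariance; a quantitative test of *de-differentiation* — does
the shared variance across tracts grow with age?; mediation of the age–FA
association through neurite density and orientation dispersion; and
penalized-regression screening of collinear brain predictors of age.
Because real cohort data are access-controlled, every stage is exercised
end-to-end on simulated cohorts whose generating parameters are known, so
estimator correctness is verified by parameter recovery.

## The core model

For diffusion measure *Y* in tract *t* and subject *i* (22 core tract
entries per measure):

```
Y[t]_i = v[t] + a1[t]·age_i + a2[t]·age_i² + a3[t]·sex_i
         + l1[t] · (1 + l1m·age_c_i) · g_i
         + l2[t] · (1 + l2m·age_c_i) · u[t]_i
```

where *g* is the measure's general factor and *u*[t] the tract-specific
unique factor (both standard normal given covariates), and the
tract-invariant interaction parameters `l1m`, `l2m` moderate the general
and unique loadings by centered age (a tract-specific variant estimates
them per tract).  The communality of tract *t* at age *a*,

```
h[t](a) = s/(s+u),   s = (l1[t](1+l1m·a_c))²,   u = (l2[t](1+l2m·a_c))²
```

rising with age is the de-differentiation signature.  The package fits the
unmoderated model by profiled maximum likelihood, the moderated model by a
per-subject likelihood with analytic gradients, summarizes `h(a)` at
5-year anchors with delta-method CIs and cubic-spline interpolation, and
confirms the trajectory non-parametrically with kernel-weighted local
factor fits (LOSEM).  See `docs/methods.md` for the full account.

## Worked example

```python
import dediffwm as d

# simulate the default cohort: 5,455 raw subjects, staged exclusions
gm = d.default_generating_model()
subjects, table = d.generate_cohort(gm, n_raw=5455, seed=1)
retained, counts = d.apply_exclusion_cascade(subjects)
table = table.subset_subjects(retained["subject_id"])
print(dict(counts))
# {'raw': 5455, 'early_phase': 567, 'qc_fail': 1314,
#  'neuro_diagnosis': 59, 'outlier': 2, 'final': 3513}

# one-factor model of FA across the 22 core tract entries
fit = d.fit_one_factor(table, "FA")
print(round(fit.variance_explained_, 3))      # 0.418

# age-moderated fit: how much more variance does the factor explain at 75?
mfit = d.fit_moderated_factor(table, "FA", base_fit=fit)
delta, se = d.communality_delta(mfit)
print(round(delta, 1), round(se, 1))          # 14.0 2.3

# minimal detectable bivariate association at 80% power
print(d.detectable_effect(1000, 0.05, 0.80))  # 0.088
print(d.detectable_effect(3513, 0.05, 0.80))  # 0.047
```

The exclusion counts show the staged cascade (early-phase scans, QC
failures, neurological diagnoses, extreme outliers) leaving the analysis
sample of 3,513.  `variance_explained_` is the mean share of each tract's
covariate-adjusted variance captured by the general FA factor (the default
generator is calibrated near 41%).  `communality_delta` is the fitted
increase, in percentage points, of mean communality between ages 45
and 75 — the de-differentiation effect (the default FA ground truth of
0.008/yr loading moderation implies ≈ 11–14 pp, and the fitted value here
is 14.0 ± 2.3).  The power utility reports the smallest standardized
correlation detectable two-sided at α = 0.05 with 80% power.

The same analyses are available from a shell:

```bash
dediffwm simulate --n-raw 5455 --seed 1 --out cohort/
dediffwm factors --table cohort/ --measure FA --residual-pairs auto --out fa.json
dediffwm dediff --table cohort/ --measure FA --losem --out dediff_out/
dediffwm run-all --seed 7 --out run/
```

`run-all` executes every stage (tract effects → factors → pathway models →
mediation → elastic-net age prediction → de-differentiation) and writes
tidy TSV/JSON artifacts with a checksummed report; a full run at n = 3,513
takes about a minute and a half on one CPU.

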