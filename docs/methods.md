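# Methods

This document records the statistical model, the estimation and numerical
choices, the scope of the synthetic generator, and known limitations.

## 1. Synthetic cohort generator (`devprofiles.cohort`)

### Latent model

Each subject belongs to one of K₁ wave-1 profiles drawn from cluster weights
`cluster_weights_w1`. A profile is a prototype vector in the m-dimensional
factor space (`cluster_prototypes_w1`, default 7 profiles × 6 factors). The
subject's wave-1 latent factor score is the prototype plus isotropic Gaussian
noise (`noise_sd`, default 0.5). Wave-2 membership is drawn from a row of the
profile-to-profile `transition_matrix`; the wave-2 latent score is the wave-2
prototype (`cluster_prototypes_w2`, default 6 × 6) plus independent noise.

Observed items load on the factors through a common loading matrix with a
simple structure: each item loads `loading_strength` (default 0.7) on one
factor, with unit-variance unique error. The same loading matrix is used at
both waves so that factor congruence across waves is meaningful.

### Measurement levels

- **Wave 1**: continuous visual-analogue ratings. Latent item scores are
  affinely mapped to the instrument range (default 0–100 mm, three latent SDs
  to half range) and clipped at the bounds.
- **Wave 2**: 4-point ordinal ratings obtained by thresholding the latent item
  scores at fixed quantile cut points (`ordinal_levels_w2`).

### Data problems planted with ground truth

- **Missingness**: completely at random at `missing_rate` (default 2%) per
  cell, planted after generation with its own seed stream.
- **Univariate outliers** (`n_uni_outliers`, default 10): one cell moved to
  mean + 5 SD of its item — a data-entry-style error that can exceed the
  declared instrument range.
- **Multivariate outliers** (`n_multi_outliers`, default 10): a whole row
  shifted along a low-variance direction of the sample covariance, scaled so
  its squared Mahalanobis distance exceeds the chi-squared screening cutoff
  while each coordinate stays within 2.9 SD (so the univariate screen alone
  cannot find it).
- **Covariate signal**: subjects transitioning into the wave-2 emotional
  profile receive a small negative income shift (`covariate_income_shift`),
  giving the predictor-contrast stage something real to find.

`GroundTruth` records true labels at both waves, latent scores, loadings, and
planted outlier ids, enabling planted-versus-detected comparisons.

### Randomness

All randomness flows from `numpy.random.SeedSequence([seed, code])` with a
distinct code per purpose (latent draws, item noise per wave, missingness,
outliers, covariates, parallel analysis, bootstrap, TSVQ restarts, hybrid
tree, permutation test). Streams are therefore independent and each stage is
reproducible in isolation; reruns with the same configuration are
byte-identical (report files contain no timestamps; wall time goes to the log
only).

### Scope

The generator reproduces the data *regime* of a two-wave behavioural cohort —
mixed measurement levels, a dominant low-problem cluster, modest factor
strength, realistic missingness and error rates — not any particular
dataset. Conditions outside scope: non-simple-structure loadings, non-MCAR
missingness, item-level drift between waves, and nested (school/family)
dependence.

## 2. Preprocessing (`devprofiles.preprocess`)

Pipeline order (fixed): missingness screen → EM imputation → outlier screen →
discretisation of analogue items.

- **Missingness screen**: subjects with more than `max_missing = 5` missing
  items are excluded and counted in the CONSORT summary.
- **Imputation**: multivariate-normal EM, grouping subjects by missingness
  pattern for vectorised E-steps. The M-step covariance includes the expected
  conditional scatter of the imputed cells, so marginal variances and
  covariances are preserved rather than shrunk. Convergence when the largest
  parameter change falls below 1e-6 (200-iteration cap). Imputed ordinal cells are rounded to the
  nearest valid level; analogue cells are clipped to the instrument range.
- **Outlier screen** (item level, after imputation): univariate |z| > 3 on any
  item, then multivariate squared Mahalanobis distance above the chi-squared
  (1 − 0.001) quantile with p degrees of freedom. Under normality the
  univariate rule alone excludes ≈ 1 − (1 − 0.0027)⁴⁰ ≈ 10% of subjects at
  40 items; this is a property of the published rule, not a bug, and the
  CONSORT counts report it transparently.
- **Discretisation**: analogue items are cut into 4 ordinal levels at the
  deepest local minima of a Gaussian KDE (Silverman bandwidth, 512-point
  grid); if the KDE has no interior minima (unimodal), equal-probability
  (tercile-style) cuts are used and flagged.

## 3. Polychoric correlations (`devprofiles.polychoric`)

Two-step maximum likelihood: thresholds per item from the inverse-normal
cumulative margins; then the correlation of each pair maximises the bivariate
likelihood of the observed contingency table over ρ ∈ (−0.999, 0.999) by
bounded scalar minimisation. Cell probabilities use a vectorised port of
Genz's BVND algorithm for the bivariate normal CDF (Gauss–Legendre panels,
accuracy ~1e-14), which dominates runtime and makes a 40-item matrix feasible
in seconds. The matrix is forced symmetric with unit diagonal; a
nearest-positive-semidefinite projection (eigenvalue clipping) is applied if
any eigenvalue is negative. Validation: recovery within ±0.05 of the true ρ
at n = 5000 across the grid of table sizes, and near-zero estimates under
independence.

## 4. Factor analysis (`devprofiles.factors`)

- **Extraction**: minimum residual (minres). Uniquenesses start at
  1 − squared multiple correlation and are optimised by L-BFGS-B on the sum of
  squared off-diagonal residuals; loadings come from the eigendecomposition of
  the reduced correlation matrix. Solutions with any uniqueness ≤ 0.001 are
  flagged `heywood`.
- **Rotation**: varimax on the raw criterion (`normalize=False`), iterated via
  the SVD update until the criterion gain falls below 1e-8. Raw varimax was
  chosen because the generator's items have equal communalities in
  expectation, making Kaiser row normalisation a no-op in the data regime and
  simpler to reason about; the rotation routine accepts `normalize=True` when
  row-weighted rotation is wanted.
- **Factor count**: Horn's parallel analysis. Null datasets are ordinal tables
  resampled to match the observed item margins, factored the same way (on
  polychoric correlations); the suggested count is the number of observed
  eigenvalues above the 95th percentile of the null eigenvalues.
- **Scores**: Thurstone regression scores, re-standardised per factor to unit
  variance. A direct consequence: each factor-score column has mean exactly 0,
  so the *domain main effect* in the downstream group × domain ANOVA is 0 by
  construction — the scientific signal lives in the group and interaction
  effects. This is stated here once so the F = 0, p = 1 rows in
  `results/06_inference.json` are not read as an error.
- **Stability**: bootstrap resampling of subjects; factor match by greedy
  maximum Tucker congruence with sign alignment; reported as mean congruence
  per factor.

## 5. Hybrid clustering (`devprofiles.clustering`)

Follows the mutual-cluster/TSVQ hybrid of Chipman & Tibshirani:

1. **Mutual clusters**: groups whose maximum within-group distance is smaller
   than the minimum distance to any point outside; found from an
   agglomerative sweep with a provable check. Mutual clusters are contiguous
   in any reasonable tree and must never be broken.
2. **TSVQ**: top-down 2-means splits (k-means with `n_restarts` restarts per
   split, seeded deterministically), giving a binary dendrogram with
   within-node SSE heights.
3. **Hybrid**: TSVQ is run on mutual-cluster centroids (weighted by size),
   then each mutual cluster is expanded in place by running TSVQ inside it,
   with child heights capped at the parent height so the dendrogram is
   monotone.

Cluster-number diagnostics: Calinski–Harabasz across tree cuts (with percent
change and local extrema flagged), silhouettes (per subject, per cluster,
overall). Cluster description: per-factor means and Cohen's d versus the
sample mean with star labels (0.2 / 0.5 / 0.8).

## 6. Partition comparison (`devprofiles.compare`)

Fowlkes–Mallows B = T / √(P Q) on the shared subjects, where T, P, Q are the
matching-pair counts from the k_a × k_b contingency table. The null
distribution permutes one labelling; the two-sided p-value is the add-one
permutation p, p = 2·min(r_low, r_high)/(n_perm + 1), capped at 1. Note the
granularity: with n_perm permutations the smallest achievable p is
2/(n_perm + 1) and the achievable two-sided rejection rate at α = 0.05 is
2⌊0.05(n_perm + 1)/2⌋/(n_perm + 1) (e.g. 0.048 at 999 permutations); the
calibration tests account for this.

## 7. Transition inference (`devprofiles.transitions`)

From the cross-tabulation of shared subjects: per-row chi-squared
goodness-of-fit against an equal split over the K₂ destination profiles
(warning when expected counts drop below 5), and cellwise z-tests of the row
proportion against p₀ = 1/K₂ with Bonferroni adjustment over the full
K₁ × K₂ family, flagging cells `over` or `under`. Predictor contrasts compare
subjects making a flagged transition with everyone else on each covariate
(pooled-variance t, Bonferroni over covariates, Cohen's d).

## 8. ANOVA, sphericity, and power (`devprofiles.inference`)

- **Mixed (split-plot) ANOVA** of group (between) × domain (within, m = 6
  factor scores): classical sum-of-squares decomposition. Verified against
  `pingouin.mixed_anova` to machine precision on F, df, and p.
- **Mauchly's test** is computed on the *pooled within-group* covariance of
  the Helmert-contrast scores with df = n − g (g groups), which respects the
  between factor. `pingouin`'s Mauchly pools across groups without removing
  group means, so its W differs by design; our version matches a hand-built
  oracle. Greenhouse–Geisser ε corrects the within dfs; simulation shows the
  corrected within-effects test holds its nominal size (measured type-I 0.052
  in [0.03, 0.07] under strong heteroscedasticity where the uncorrected test
  reaches 0.069).
- **Power**: noncentral-F with numerator df = m, denominator df = N − m − 1,
  noncentrality λ = f²N. This convention reproduces the planning triplet used
  in the analysis (minimum N = 2093 for f = 0.10, and minimum detectable
  f = 0.0415 / 0.0556 at N = 12134 / 6744, all at α = .05, power .95).

## 9. Numerical choices

- Bounded scalar optimisation (Brent) for polychoric ρ; L-BFGS-B with
  uniqueness bounds [0.001, 1] for minres; SVD-based varimax updates.
- KDE on a 512-point grid over the declared instrument range.
- EM tolerance 1e-6 on the max absolute parameter change, 200-iteration cap;
  polychoric ρ solved to xatol 1e-6.
- Report floats are rounded to 6 significant digits at serialisation;
  computations are double precision throughout.
- All seeds derive from `SeedSequence` spawn keys; no global RNG state is
  used or mutated.

## 10. Limitations

- **The default cohort is hard by design.** With a 50% normative cluster,
  overlapping prototypes and noise_sd = 0.5, even an oracle k-means on the
  true latent scores reaches only ≈ 0.80 ARI; the full pipeline (measurement
  error, discretisation, estimated scores) reaches ≈ 0.12–0.17, and the
  Fowlkes–Mallows test on the default run is non-significant (p ≈ 0.38).
  Recovery validation therefore uses separable planted profiles (acceptance
  tests reach ≈ 0.97 ARI); the defaults were deliberately *not* tuned to make
  the pipeline look better.
- The univariate |z| > 3 screen excludes ~9–10% of clean subjects at 40
  items; it is applied as published and reported in the CONSORT counts.
- Polychoric estimation assumes bivariate-normal latent responses; EM
  imputation assumes multivariate normality and ignorable missingness.
- The domain main effect is structurally zero for standardised factor scores
  (see §4); between-domain severity comparisons require unstandardised scores.
- Silhouette values are low (≈ 0.10) in the continuous-overlap regime; they
  are reported as relative, not absolute, evidence.
- Mutual clusters become rare as n grows (a known property); the hybrid tree
  then degenerates gracefully toward plain TSVQ.
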