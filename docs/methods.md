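# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `glycomet`.

## Study design being modeled

Three weight-loss intervention arms (IMI, BAND, RYGB; 25 participants each
by default), fasting plasma sampled at baseline and one year, untargeted
metabolomics (364 features by default, 153 flagged as chemically
identified, "known"), and two glycemic endpoints — fasting plasma glucose
and HbA1c — analyzed as percent change (follow-up − baseline)/baseline.
Arms are not randomized, so all models adjust for sex, baseline age,
baseline BMI, and weight loss; weight loss is additionally adjusted so
metabolite effects are interpretable as weight-loss-independent.

## Preprocessing

Order of operations: **sum-normalize → presence-filter → impute →
percent change → standardize**.

- *Sum normalization* divides each sample by its summed intensity over
  known metabolites (unknown features ride along on the same factor), the
  standard total-intensity convention for GC-MS peak heights.
- *Presence filter*: a metabolite is retained iff it has a non-missing,
  positive value in ≥ 50% (configurable) of the samples of **every** arm.
- *Imputation*: remaining missing values are set to half the metabolite's
  minimum observed value, the usual limit-of-detection convention; it also
  keeps percent change defined.
- *Standardization* uses the sample SD (ddof = 1, as R's `scale`), and is
  applied **last**, to the scan exposure only: the percent change of an
  already mean-centered variable would be ill-defined. The order is
  recorded in each run's manifest because other orderings are defensible.
- *Weight loss* is coded as the signed fraction
  (weight₁ − weight₀)/weight₀ (negative when weight is lost), matching the
  percent-change convention of the outcomes. This coding is a package
  choice (kg-scale coding would only rescale the covariate's coefficient).

## Interaction scan

Per metabolite, one pooled OLS fit
`y ~ 1 + m + G + m×G + covariates` with IMI the reference arm. Group-
specific slopes β\*(g) = β_m + δ_g, contrasts β†(g₂ vs g₁) = δ_{g₂} −
δ_{g₁}; SEs and two-sided t tests (residual df of the pooled model) come
from the coefficient covariance via the linear-combination rule, so
RYGB-vs-BAND needs no refit and the three contrasts are mutually
consistent by subtraction — the identity β† = β\*(g₂) − β\*(g₁) holds to
1e−10 and is tested. A pooled model (common residual variance) rather than
per-arm fits is used because the contrast of interest *is* the interaction
coefficient of the pooled model. An optional extra binary covariate (e.g.
pre-intervention hypoglycemic-drug use) supports sensitivity analyses.

Metabolites whose fit fails (constant exposure in an arm, rank deficiency)
are flagged in the output and excluded from q-value families, never
silently dropped.

### Storey q-values

π₀ is estimated on the grid λ = 0.05, 0.10, …, 0.95 as
π̂₀(λ) = #{p > λ}/(m(1 − λ)), smoothed by a cubic least-squares fit in λ
and evaluated at λ = 0.95, then clamped to [1/m, 1]. The cubic polynomial
is this package's concrete choice of the "smoother" variant (a heavily
smoothed natural cubic spline and a cubic polynomial coincide in practice
on a 19-point grid). For m < 100 the smoother is unstable and π̂₀ = 1 is
used, which makes the q-values exactly Benjamini–Hochberg — an identity
that is tested property-based. q-values are computed per outcome ×
contrast family (6 families per scan pair of exposures) so the family
matches how significant counts are reported.

## Differential networks

Built on covariate-residualized (sex, age, BMI, weight loss; OLS residuals
per metabolite, a projection tested against the explicit hat-matrix
oracle), column-standardized abundances, pooling both timepoints within
each arm (50 samples/arm at default size); pooling is the default because
the co-regulation structure of interest is an arm property, not a
timepoint property, and it doubles the effective sample size.

- *Adjacency*: unsigned, a_ij = |pearson r|^p. Unsigned is the
  conventional default when no sign convention is stated.
- *Soft power*: smallest p in 1..20 whose scale-free fit reaches R² ≥ 0.8
  with negative slope (log₁₀ bin frequency on log₁₀ mean connectivity, 10
  bins); fallback 6 with a machine-readable warning. When run as a
  pipeline, one power is chosen on the pooled residualized matrix and
  shared by all arms, so MDC compares adjacencies at a common threshold.
- *TOM*: TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  verified against a triple-loop oracle to 1e−12.
- *Modules*: average-linkage clustering of 1 − TOM with a **static** cut
  (default height 0.75, min size 5). Static rather than dynamic-hybrid
  cutting keeps the procedure fully specifiable and deterministic at a few
  hundred features; both knobs are config fields. Modules get size-ranked
  WGCNA color names (largest = turquoise, then blue, …; ties broken by
  smallest member id); the colors are cosmetic. "grey" marks unassigned
  features. The hub is the member with maximal intramodular connectivity,
  ties broken lexicographically.
- *MDC*: the signed sum over module pairs of adjacency differences,
  MDC(A,B) = Σ_{i<j}(a_ij^A − a_ij^B). A signed statistic (rather than a
  connectivity ratio) is the primary definition because gain *and* loss of
  connectivity need a sign; the ratio Σa^A/Σa^B is reported as a secondary
  column. Significance: pooled samples, arm labels permuted preserving
  sizes (default 1000 permutations), two-sided add-one estimator
  p = (1 + #{|T_perm| ≥ |T_obs|})/(n_perm + 1), so p = 0 is impossible and
  the floor is 1/1001 at defaults. GOC = positive statistic with p < 0.05;
  LOC = negative with p < 0.05.

## Pathway enrichment

One-sided (over-representation) Fisher's exact test — the hypergeometric
tail P(X ≥ k) on the 2×2 table restricted to the background — because
enrichment is inherently a right-tail question. The background is the
known-metabolite set only; unknown spectral features have no pathway
identity. Node importance is betweenness centrality (shortest-path count
form, computed per connected component) normalized to sum to 1 within the
pathway, with a uniform fallback when all centralities are zero (≤ 2
nodes, complete or edge-free graphs); the impact score of a hit set is the
sum of its importances. Pathway p-values are reported raw (an optional BH
column is included); compounds are matched by case-folded identifier and
unmatched hits are returned explicitly. Pathway definitions are user-
supplied GMT + edge-list TSV files; no online database access.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *structure* the
analysis assumes and plants known truths.

- **Covariates**: age ~ Normal(51, 8) truncated to [21, 70]; sex
  Bernoulli(0.84 female); baseline BMI ~ Normal(arm mean 43.3/45.7/48.5,
  SD 6) truncated at ≥ 33; baseline weight ~ Normal(120/123/133, SD
  26/16/20) kg. These match the reported cohort moments.
- **Weight loss**: fractional loss ~ Normal(0.117/0.195/0.353 for
  IMI/BAND/RYGB, SD 0.05), clipped to [0.01, 0.6]; follow-up weight is
  back-computed. The arm means are the reported mean weight changes
  divided by baseline weights.
- **Metabolites**: lognormal peak heights exp(μ_j + 0.5·z), μ_j ~
  Normal(8, 1), so abundances are positive and sum normalization is well
  defined. Planted modules are equicorrelated latent-Gaussian blocks with
  an arm-specific ρ ∈ [0, 1); on the abundance scale the correlation is
  mildly attenuated (ρ = 0.8 → ≈ 0.78 at log-SD 0.5), which the recovery
  tolerance (±0.1) absorbs. Defaults plant three modules: ρ = 0.8 in RYGB
  only (a GOC module), ρ = 0.6 everywhere, and ρ = 0.7 in IMI/BAND but 0.1
  in RYGB (a LOC module).
- **Outcomes**: percent changes are generated directly from the linear
  predictor — arm intercept + Σ planted slope(arm) × standardized exposure
  + 0.3 × weight-change fraction + Normal(0, 0.1) noise — where each
  exposure is rebuilt exactly as the scan will see it (sum-normalized,
  baseline level or percent change, standardized). The fitted model is
  therefore exactly the generating model, which is what makes 3-SE
  recovery coverage a meaningful check. Arm intercepts are set so the mean
  percent changes match the reported cohort (FPG ≈ −5/−11/−22%, HbA1c ≈
  −7/−8.5/−24%); baseline FPG/HbA1c are lognormal around the reported arm
  medians and follow-ups are back-computed.
- **Missingness** is off by default (the emulated dataset is complete
  after its presence filter); an optional missing-at-random rate exercises
  the filter and imputation paths.
- **Determinism**: one seed sequence per run, spawned into per-stage child
  streams; identical seeds give bit-identical outputs.

What the generator does **not** emulate: batch effects and QC-based
correction (single batch by design), medication use, within-participant
correlation between timepoints beyond the planted module structure,
heavy-tailed or compositional noise beyond lognormality, and non-random
arm assignment correlated with metabolites. Passing recovery tests
therefore shows the estimators are correct and calibrated under the
assumed data-generating process, not that real cohorts satisfy it.

## Operating-characteristic studies (problem sizes)

The acceptance script and test suite compute, at these sizes chosen to
give stable estimates in seconds-to-a-minute on one CPU:

- type-I error: one null scan of 1000 metabolites, 25/arm → 3000 contrast
  p-values; expected rejection rate 0.05, accepted band [0.03, 0.07];
- planted-contrast recovery: 100 seeds, 200/arm, noise SD 0.1, planted
  contrast 2.0; coverage of ±3 SE required ≥ 95%;
- MDC calibration: 200 exchangeable-null simulations (ρ = 0.3 both arms,
  module 10, 100/arm, 1000 permutations); call rate ≤ 8%, p-values
  KS-uniform; power: 50 simulations at ρ 0.8 vs 0.0, GOC with p ≤ 0.01
  required in ≥ 95%;
- module recovery: two ρ = 0.8 blocks of 10 + 20 noise features, n = 100,
  soft power 4; ARI ≥ 0.9. Power 4 is used in this experiment because at
  power 6 the expected within-block TOM (≈ 0.26) sits exactly on the
  default cut boundary (1 − 0.75), so the experiment would measure
  rounding rather than recovery;
- exact oracles: TOM vs triple loop (1e−12), Storey(π₀=1) vs BH, Fisher vs
  enumerated hypergeometric tail, betweenness closed forms on path/star.

## Known limitations

- The static tree cut at height 0.75 is conservative at soft power 6:
  modules with within-arm |r| ≲ 0.7 land in "grey". Loosening the cut or
  lowering the power is a config decision, not a code change.
- The MDC statistic's scale depends on module size and soft power; values
  are comparable only within a run. The permutation p, not the statistic's
  magnitude, carries the inference.
- π₀ estimation on fewer than ~100 tests falls back to BH; q-values are
  then conservative.
- Percent change requires positive baselines; zero/negative baselines are
  rejected rather than patched.
- The generator's between-timepoint independence of metabolite draws means
  the "change" exposure is noisier than in real repeated measures; scan
  power at study scale is correspondingly conservative.
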