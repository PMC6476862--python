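# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of
`onsetmod`. Notation: y is age of onset (ADAOO, years), K the n×n
pairwise-relatedness matrix, sigma_g2/sigma_e2 the polygenic and
residual variances (years²), delta = sigma_e2/sigma_g2.

## Mixed-model association

### Model and fitting

Each association fit is the one-random-effect LMM

    y = X b + u + e,  u ~ N(0, sigma_g2 K),  e ~ N(0, sigma_e2 I)

with fixed effects X = intercept + sex (indicator for male, female
reference) + years of education (continuous by default; a 4-level
education grouping is available as a config switch, matching how the
descriptive analyses bin education). Variance components are
estimated by REML. Because only one random effect is present, the
restricted likelihood profiles to a one-dimensional function of
delta: after the spectral decomposition K = U L U' (done once per
scan), each evaluation is a weighted least-squares solve on the
rotated data (U'y, U'X) with weights 1/(lambda_i + delta). The
optimizer is a 17-point coarse grid on log10(delta) in [-4, 4]
followed by bounded Brent refinement between the bracketing grid
points (xatol 1e-6). ML log-likelihoods are computed from the same
profile and reported alongside REML.

### Small-sample inference

Wald t-tests with plug-in REML components and residual df are
anticonservative in small, strongly related samples: in our
calibration experiment (n=100, pedigree kinship, 5,000 null marker
tests) the naive test rejected at 6.6% for nominal 5%, while the same
test with the true variance components held 5.05%. The default
inference therefore applies a Kenward–Roger-type (Kackar–Harville)
adjustment to Cov(beta_hat) and Satterthwaite denominator df, both
computed from the REML information matrix of (sigma_g2, sigma_e2) —
cheap in the rotated basis, where V is diagonal and all traces are
elementwise O(n² p). After the adjustment the same experiment
rejects at 5.0%. When variance components are supplied as known
(`fix_components`), the fit is exact GLS and residual df apply.

### Genetic codings

On minor-allele dosage d ∈ {0,1,2}: additive d, dominant 1{d≥1},
recessive 1{d=2}. A per-marker orientation flip (`reference="major"`)
maps d → 2−d first, so a "dominant" model can equally group genotypes
around the major allele — modifier alleles in the literature are
reported in both orientations, and the two codings span all
carrier-type groupings of a biallelic genotype. Samples missing at
the tested marker are dropped for that marker only (the kinship
submatrix is re-decomposed when this happens).

### Multiple-testing correction

`fdr_adjust` implements the Benjamini–Hochberg step-up rule literally
(adjusted p_(i) = min over the tail of min(1, m·p_(j)/j)); the
statsmodels implementation serves as an independent cross-check in the
unit suite. The extreme-value correction permutes the GLS residuals
of the covariate-only null model, recomputes every marker's |t| per
permutation with the variance components held at the null-model
estimates (a vectorized GLS, so the whole null distribution is a few
matrix products), records the per-permutation maximum over the panel,
and fits a generalized-extreme-value distribution to the maxima by
maximum likelihood. The adjusted p is the fitted upper-tail
probability of the observed statistic, floored at the raw p and capped
by the empirical add-one permutation p (the GEV is trusted only to
extrapolate below the empirical floor, never above it). If the GEV
fit fails, the empirical permutation p is used and flagged. Observed
statistics for this correction are computed with the same fixed-delta
machinery as the permuted ones, for comparability; the per-marker
REML Wald p remains the primary "raw" p.

### Stepwise multi-locus selection

Forward/backward search, at most `max_steps` (default 10) forward
additions. The selection criterion is an extended BIC,
-2·loglik_ML + k·log n + 2·gamma·log C(m, k) with gamma = 0.5,
evaluated on the ML profile likelihood: REML likelihoods are not
comparable across fixed-effect designs, so although the variance
components come from the same profiling machinery, model comparison
uses ML. (The criterion is a pluggable callable; eBIC is the default
and the only built-in.) A candidate whose coded column is numerically
collinear with the current design (relative residual norm < 1e-10) is
skipped, which also resolves duplicated markers deterministically in
favor of the earlier panel position. After each addition, a backward
sweep removes any included marker whose exclusion improves the
criterion. Missing coded genotypes are mean-imputed during the
search so every candidate model is scored on the same analysis set;
the reported final fit (joint REML, adjusted Wald tests) uses
complete cases for the selected markers.

Variance explained: the phenotype is residualized on the covariates;
selected markers then enter in selection order, each credited with the
reduction in residual variance given its predecessors, as a fraction
of covariate-adjusted Var(y). The sequential shares sum exactly to
the joint R² of the genetic terms, so shared signal is credited to the
earlier-selected marker — the convention matching "proportion of
variance explained by each marker" reporting.

### Heterogeneity (covariate-specificity) tests

Whether a marker's effect differs by sex or education group is tested
by a likelihood-ratio test (ML) of marker×group interaction terms
against main effects only, chi-square with (levels−1)·1 df. Groups
containing no carriers of the coded allele are excluded (df reduced,
noted in the output). The df convention is the implemented one;
published tables of this kind are not always internally consistent,
and no attempt is made to reverse-engineer any other construction.

## Two-locus epistasis

`adjusted_cell_means` residualizes onset on the covariates by OLS
(grand mean re-added) and tabulates the ≤ 3×3 genotype-cell means on
complete cases. `full_two_locus_fit` decomposes the cell-mean surface
by n-weighted least squares on additive scores (−1, 0, 1), centered
heterozygosity dominance scores (1{het} − ½), and their four products
(aa, ad, da, dd); unidentifiable columns on the occupied cells are
dropped and reported, and the joint test of the epistatic terms is an
F test against the pooled within-cell mean square.

Inference for cell-mean contrasts separates two resampling schemes
that are often conflated: confidence intervals come from a
nonparametric percentile bootstrap (resample individuals with
replacement, re-run the covariate adjustment, recompute the
contrast), while p-values come from permutation of the target
marker's genotype labels against the (other genotype, covariates,
phenotype) tuples, with the add-one estimator
p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (B_valid + 1), which can never
return 0. A pure bootstrap "null" for a mean difference is
ill-defined without a null-imposing device, hence the split. B
defaults to 10,000; calibration experiments use reduced B with the
same estimator. Permuted replicates with an empty contrast group are
excluded from both numerator and denominator (their occurrence is
independent of the phenotype, so this does not bias the test).
Contrasts whose carrier or non-carrier group falls below `min_cell_n`
(default 3 — cells in a ~78-person cohort are small, and 3 is the
smallest group for which a mean difference is even nominally
meaningful) are flagged inconclusive with no p reported. The default
contrast family in `pairwise_screen` is carrier-vs-non-carrier of
each marker within each genotype stratum of the other, plus a
per-pair verdict from the epistatic F test at 0.05.

The permutation treats individuals as exchangeable and therefore
ignores kinship; a relatedness-preserving permutation scheme is out
of scope and the limitation should be kept in mind when permutation
p-values approach a decision boundary.

## Onset-distribution descriptives

`fit_mixture` is a univariate Gaussian-mixture EM with multiple random
restarts (default 20, seed-expanded substreams; initial means drawn
from the data, initial sds at the sample sd), variances floored at
(0.01·sd(y))² to block degenerate spikes, and the EM monotonicity of
the log-likelihood asserted at every iteration. Components are
reported sorted by mean. k = 1 is closed form. Model choice across k
uses BIC with 3k−1 free parameters; the raw log-likelihood is
reported alongside but cannot itself select k (it is nondecreasing in
k by construction), so "choose k by likelihood" prescriptions are
implemented as BIC. Convergence is |Δ loglik| < 1e-7 within 2,000
iterations; with a floored, nearly-degenerate component EM can crawl,
in which case the best partial fit is returned with a warning and
`converged=False`.

Early/late dichotomization splits at 48 years with the late side
inclusive (onset ≥ 48 is "late"). Group comparisons: two-sample t
with pooled variance by default (classical n1+n2−2 df bookkeeping;
Welch by flag), one-way ANOVA across education groups, OLS slope/R²
for onset on years of education.

## Synthetic cohorts

The generator emulates the statistical structure of a founder-pedigree
modifier study; it is the test bed for everything above.

- **Pedigree**: discrete generations from a small founder pool
  (default emulation: 20 founders, 4 generations, final generation =
  the analyzed cohort). Partner choice is biased toward relatives
  with probability `endogamy` (default 0.5), with weights
  proportional to current relatedness. Kinship truth is the additive
  relationship matrix from the recursive tabular method
  (A_ii = 1 + F_i; diagonals exceed 1 under inbreeding), restricted
  to the cohort. With depth 1 the cohort is unrelated founders and
  K = I.
- **Genotypes**: founders binomial at Hardy–Weinberg from the
  configured MAFs; children inherit one allele per parent (gene
  dropping); markers independent (no LD). Missingness is MCAR at
  `missing_rate`. Because candidate panels are ascertained to
  segregate in the study sample, a marker whose realized cohort MAF
  falls below 1% through founder-bottleneck drift is redrawn
  (`min_cohort_maf`, 0 disables); without this, a MAF-0.046 variant
  is monomorphic in ~40% of 20-allele founder pools, which no
  candidate-panel study would retain. The returned matrix is
  oriented to the in-sample minor allele exactly as the file loaders
  orient theirs; `MarkerInfo.flipped` records drift flips, and
  phenotypes are always generated on the configured allele.
- **Phenotype**: y = mu + sum(beta·code) + sex/education effects
  + u + e with u ~ MVN(0, sigma_g2·K), e iid. The default emulation
  plants three onset-delaying variants — +8.21 y dominant at MAF
  0.046, +3.68 y dominant at 0.396, +3.27 y recessive at 0.339 — with
  null sex/education effects, a 60% female cohort, and education
  groups at 5/55/34/6% (none/elementary/high school/tertiary).
- **Calibration of the defaults**: mu = 45.01, sigma_g2 = 7.0,
  sigma_e2 = 6.5. These were fixed once against the generator's own
  pedigree process: segregation-conditioned gene dropping through 20
  founders gives the causal terms a mean of 3.79 y and a sample
  variance of ~11.0 y² (≈ 46% of the total, matching the oligogenic
  share such studies report), relatedness shrinks the polygenic
  *sample* variance to ≈ 0.92·sigma_g2, and mu supplies the
  remainder of the 48.8-year target mean. Over 200 seeds the
  emulation cohort realizes onset mean 48.74 and sd 4.80–4.94 —
  i.e., the targets 48.8 ± 4.9 within Monte-Carlo error.
- **QC fixtures**: `fixture_suite` emits a clean 65-marker cohort
  (every marker passes default QC by construction, via per-marker
  rejection sampling) and a 70-marker variant appending five markers
  that each violate exactly one rule: monomorphic (MAF 0 < 1%),
  declared-triallelic (allele-count rule, evaluated on the declared
  alleles so the monomorphic marker does not double-fail), call rate
  66/78 < 0.90, MAF 1/156 < 0.01, and a no-heterozygote marker at
  MAF 0.5 (Hardy–Weinberg rule).
- **Power**: `power_by_simulation` is the Monte-Carlo rejection rate
  of the single-locus mixed-model test for a chosen causal variant,
  with a Clopper–Pearson CI.

What the generator does **not** emulate — and hence what passing
tests do not establish about real data: linkage disequilibrium
between panel markers, genotyping error beyond MCAR missingness,
onset censoring/survival sampling (everyone has an observed onset),
ascertainment of extreme-onset individuals, and the real pedigree's
loop structure (only "elevated relatedness" is matched, not any
published genealogy).

## Quality control

Exclusion rules, with boundaries inclusive on the passing side:
Hardy–Weinberg p < 0.05/m (m = markers entering QC, not survivors;
1-df chi-square at the ML allele frequency by default, conditional
exact test by flag; monomorphic markers return p = 1), call rate
< 0.90, declared allele count ≠ 2, MAF < 0.01. All violated rules
are listed per marker; `apply_qc` is idempotent. Allele frequencies
are the ML counting estimators; all-missing markers report undefined
(not zero) frequencies. The kinship estimator is the standardized
GRM K = ZZ'/m (per-marker centering 2p, scaling sqrt(2p(1−p)),
mean-imputation of missing dosages for this computation only),
PSD-stabilized by flooring negative eigenvalues at zero; a
pedigree-derived or file-loaded matrix can be substituted, since
whether such studies use genotype- or pedigree-derived relatedness is
often unstated — both paths are first-class and tested.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → QC → kinship → scan →
multi-locus → epistasis → phenotype descriptives, persisting every
intermediate (TSV/JSON) and a Markdown + JSON report. A single
integer seed is expanded into per-operation substreams via
SeedSequence spawn keys (string keys hashed by CRC32), so partial
reruns reproduce exactly; every persisted output is a pure function
of (inputs, config, seed). Wall-clock timings go to the log stream
only, and the report echoes the configuration without the output
path, so two runs with the same config and seed are byte-identical
regardless of where they write. Partial failure stops at the failing
stage with earlier outputs intact; an empty post-QC panel aborts
cleanly with the QC report persisted.

Problem sizes in the test suite and acceptance script (null-scan
cohorts of n=100×10 markers, recovery at n=400×65, 3,000 permutation
calibration pairs, 500 bootstrap-coverage replicates, 60 mixture
seeds) were chosen so each experiment's Monte-Carlo error is small
against the property band it checks while the whole suite stays in
the minutes range on one CPU.

## Known limitations

- One random effect only; no GxE variance components, no multi-kernel
  models, no Bayesian inference.
- The EVT correction's reference construction is a GEV fit to
  permutation maxima with an empirical fallback; other published
  extreme-value constructions exist and are not reproduced.
- The stepwise criterion is eBIC; the criterion interface is
  pluggable precisely because "optimal model" criteria in this
  literature are often underspecified.
- Epistasis permutations ignore kinship (see above).
- PLINK support is the text .ped/.map dialect only; binary .bed is
  out of scope.
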