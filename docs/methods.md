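# Methods

This note documents the models, the synthetic-data generator, numerical
choices, and the design decisions taken where more than one reasonable
option existed. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The episcore procedure

The package implements the standard pipeline for constructing a
DNA-methylation proxy of a serum biomarker:

1. **Target preparation.** The serum measurement is rank-based
   inverse-normalized to remove skew, then residualized on covariates (age,
   sex, and any technical covariates supplied); the standardized residuals
   are the training target.
2. **Training.** Elastic-net regression of the target on all CpG beta
   values, with cross-validation folds defined by methylation analysis
   batch and the penalty chosen at the minimum mean cross-validated error.
3. **Projection.** The nonzero coefficients, on the raw beta scale, are
   applied to an independent cohort: the score is the weighted sum of beta
   values; no intercept is exported (all downstream uses are location/scale
   free).
4. **Validation.** Correlations with the measured biomarker and with
   estimated cell proportions; covariate-adjusted associations with known
   biomarker correlates (BMI, alcohol, deprivation linear; smoking
   proportional-odds); incremental R² of nested models; age trends with an
   age × sex interaction; association with a general cognitive factor; one
   Benjamini–Hochberg FDR family across all tests.

### Elastic net

The objective is the glmnet parameterization

(1/2N)·Σᵢ(yᵢ − b₀ − xᵢᵀβ)² + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²],

solved by cyclic coordinate descent with soft-threshold updates
βⱼ ← S(zⱼ, λα)/(1 + λ(1−α)), where zⱼ is the partial-residual inner product
divided by N. Choices:

- **Internal standardization.** Predictors are centered and scaled to
  population SD 1 (1/N denominator) before fitting; coefficients are
  returned on both scales, and the exported weights are on the raw beta
  scale so they can be applied directly to beta values elsewhere.
- **λ path.** λmax = maxⱼ|xⱼᵀ(y−ȳ)|/(Nα); 100 log-spaced values down to
  0.01·λmax (the p > n convention). α defaults to 0.5. Convergence
  tolerance 1e−7 on the maximum coefficient change per full sweep; sweep cap
  10⁵; exceeding the cap flags the fit as non-converged instead of raising.
- **Acceleration.** Sequential strong rules screen coordinates at each λ
  (candidates have gradient ≥ α(2λₖ − λₖ₋₁) at the previous solution, plus
  the active set), followed by an exact KKT check over the excluded set, so
  solutions match the naive full cyclic sweep; the equality is
  regression-tested at 1e−10. A plain-sweep mode remains available
  (`use_active_set=False`).
- **Cross-validation.** Folds are caller-supplied labels (batch).
  Standardization is recomputed inside each training complement, so no
  moment information leaks from held-out samples — the leakage-free reading
  of an unspecified convention. Columns that are constant within a fold's
  training complement are dropped from that fold's fit (coefficient pinned
  at 0) rather than failing the whole CV. The CV error is the
  sample-size-weighted mean of per-fold MSEs; its SE is the across-fold SD
  divided by √(#folds). Ties in the minimum go to the larger (sparser) λ.
- **λ selection.** Minimum-CV-error only; the 1-SE rule is deliberately out
  of scope.

### Cell deconvolution

Per sample, proportions solve min‖b − Rw‖² subject to w ≥ 0 and Σw ≤ 1 over
the probes shared with the reference. With six cell types the program is
solved **exactly by enumerating all support subsets** (each with and
without the Σw = 1 boundary active, 2·(2⁶−1)+1 candidate KKT systems) and
keeping the feasible candidate with the lowest objective. This is
deterministic, has no iterative-solver tolerance, and returns exact
vertices for pure profiles. Renormalization of rows to sum exactly 1 is
optional and off by default — downstream covariate use tolerates either,
and the flag makes the choice explicit. Samples with missing beta at shared
probes are solved on their observed probe subset.

### Statistical battery

- Continuous outcomes and exposures are standardized to SD 1 before model
  fits (configurable), so estimates are in SD units and comparable across
  traits; binary columns keep their 0/1 coding. Sex is coded female = 0,
  male = 1.
- The smoking outcome has four ordered levels (never < quit >12 mo <
  quit ≤12 mo < current) and is fit by a proportional-odds model
  (statsmodels `OrderedModel`, logit link; Newton optimization with a BFGS
  fallback; non-convergence is flagged on the result). The two-level
  collapse is verified against plain logistic regression at 1e−6, and a
  60-sample fit against a likelihood grid.
- Incremental R² fits both nested OLS models on the same complete-case
  sample and reports (R²base, R²full, ΔR²).
- The general cognitive factor is the first unrotated principal component
  of the correlation matrix of ≥3 standardized test scores, sign-oriented
  to positive (majority-positive) loadings; scores standardized to SD 1;
  variance explained = λ₁/k.
- One BH family covers every p-value of a battery run (correlations
  included); per-table families are available by flag.
- Complete-case analysis per model, with n reported per result cell.

### Rank-based inverse normal transform

Blom offset c = 3/8 with average ranks for ties:
Φ⁻¹((rᵢ − c)/(n − 2c + 1)). The offset and tie rule are the prevailing
quantitative-trait convention, documented here because they are a choice,
not a given. Missing values pass through untouched.

## 2. The synthetic-cohort generator

The generator produces the statistical structure the analysis assumes, so
every downstream stage is testable by parameter recovery.

- **Latent chronic trait L** (sample mean 0, SD 1): linear in standardized
  age, sex and smoking level plus unit Gaussian noise; the demographic
  weights (0.25, 0.20, 0.25) keep the demographic share of L modest.
- **Serum readout:** log(serum) = 0.3 + 0.8·(√f·L + √(1−f)·ε), with
  f = `chronic_variance_fraction` (default 0.5), so corr(log serum, L) = √f
  by construction and the serum trait is log-normal — exercising the
  log/rank-INT preprocessing nontrivially.
- **Probes.** All effects act on logit(beta) and are mapped back through
  the inverse logit, keeping values strictly inside (0, 1) with no clipping
  artifacts. Baselines are U(0.15, 0.85); trait-responsive (causal and
  smoking) probes draw baselines from U(0.3, 0.7) so a logit-scale effect
  is not attenuated by the sigmoid's flat tails. Technical noise is
  logit-scale Gaussian, SD 0.25.
- **Effect sizes.** Causal and smoking effects have near-homogeneous
  magnitudes (±10% around `causal_effect_sd`, default 0.15 logit units,
  random signs). The causal set thus represents one tier of individually
  detectable trait-associated CpGs — the regime in which a
  support-recovery benchmark is meaningful. With a large magnitude spread,
  a handful of strong CpGs reconstructs the latent trait on its own, the
  CV-optimal model stops early, and "sensitivity for the causal set" stops
  measuring the selector and starts measuring the heterogeneity of the
  simulated effects.
- **Cell-composition probes** are beta-scale mixtures of six reference
  leukocyte methylomes (granulocytes, NK, B, CD4T, CD8T, monocytes) with
  Dirichlet-drawn true proportions (concentration chosen to mimic
  whole-blood composition, granulocyte-dominated) plus small logit noise
  (`celltype_noise_sd` = 0.02, separate from the technical noise scale).
  The reference generator assigns each probe a random permutation of six
  evenly spaced beta levels plus jitter, guaranteeing a pairwise mean
  absolute separation ≥ 0.1 between cell types.
- **Correlated phenotypes.** BMI, alcohol units (log-normal), deprivation
  rank and a three-test cognitive battery (loading 0.7 on a common factor)
  are wired to L with configurable correlations (defaults 0.35, 0.25,
  −0.30, −0.25); marginal scales roughly follow a middle-aged population
  cohort. Smoking has four ordered categories at frequencies
  (0.52, 0.27, 0.05, 0.16).
- **Batches** are assigned with mildly uneven probabilities (weights 0.8 to
  1.2), every batch guaranteed nonempty; batch doubles as the CV fold label
  and as the cohort-splitting key.
- **Detection p-values** are U(0, 0.005) for passing cells; a
  `detection_fail_rate` fraction of cells draws from U(0.02, 1), i.e.
  strictly above the 0.01 QC threshold.
- **Determinism.** One integer master seed; all substreams derive from it
  via named `SeedSequence` spawns, so the same seed is bit-identical. The
  probe *architecture* (role assignment, baselines, effect sizes, cell
  reference) can be pinned separately via `architecture_seed`, so that two
  cohorts share an array design while their samples are independent — the
  train-here/project-there setting.
- **`null_config()`** switches off every simulated effect, giving cohorts
  in which all battery associations are null — used for FDR calibration.

What the generator does **not** emulate: Illumina probe chemistry (type
I/II design, dye bias), bimodal genome-wide beta distributions, probe-probe
correlation beyond the shared latent factors, genotype effects, and
realistic missingness patterns. Passing tests therefore demonstrate the
correctness and calibration of the *procedures*, not expected effect sizes
on real arrays.

## 3. Pipeline and problem sizes

The pipeline splits one simulated cohort batch-disjointly into a training
cohort (first ⌈B·fraction⌉ batches, default ⅔) and a projection cohort,
mirroring a two-cohort design. QC presets: probes fail at detection
p > .01 in more than 5% of samples; samples fail below a 95% call rate at
p < .01 (both thresholds are parameters — two cohort conventions are
shipped, neither privileged). Artifacts (weights TSV, scores, proportions,
JSON report, CV curve) are written with fixed float formatting, so reruns
with the same configuration and seed are byte-identical; the manifest
records a SHA-256 of the canonical configuration, the seed, library
versions, stage timings and record counts.

Benchmarks in the test suite use N = 500 samples × P = 2000 probes with 20
causal CpGs and 12 batches — large enough for the elastic net to operate in
its p ≫ n regime while a full 10-replicate recovery study runs in a few
minutes on one CPU. `scripts/acceptance.py` uses 5 replicates of the same
conditions.

## 4. Known limitations

- The enumeration-based deconvolution is exact but exponential in the
  number of cell types; it is intended for small references (≤ ~10 types).
- The elastic net supports the gaussian family only; the λ path requires
  α > 0 (for pure ridge, supply an explicit path).
- `OrderedModel`'s observed-information SEs are asymptotic; very small
  ordinal samples may flag non-convergence, which is reported rather than
  hidden.
- Score projection imputes per-sample missing cells with the probe mean of
  observed samples; probes entirely absent from a matrix contribute zero
  and are capped at 20% of absolute weight mass by default — a conservative
  documented cap, since no standard policy exists.
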