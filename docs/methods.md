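# Methods

## Data model

Input is a long-format table of phenotype records (line, environment,
trait, value), a marker dosage matrix for the lines (biallelic SNPs coded
0/1/2, missing allowed), and optionally a cross table mapping F1 hybrids to
their inbred parents.  Imbalance — lines absent from some environments —
is represented simply by absent rows.  Traits are always fitted
independently.

### Marker processing

QC retains a marker when its call rate (fraction of non-missing lines) is
at least the call-rate threshold (default 0.95) **and** its minor allele
frequency exceeds the MAF threshold (default 0.05, strict inequality so a
marker at exactly 0.05 is removed).  Remaining missing dosages are replaced
by the column mean — deterministic and accurate at the call rates the
filter enforces.  Hybrid genotypes are the arithmetic mean of the two
parental dosage rows: for inbred parents this is the expected F1 dosage,
and half-integers mark heterozygous loci.  Standardization centers each
column to mean 0 and scales to sample SD 1 (n−1 denominator); monomorphic
columns are dropped with a warning.

## Kernels

Both kernels are built from the standardized matrix X (n lines × p
markers):

* **GB (linear / GBLUP)**: K = XX′/p.  Division by p makes the average
  diagonal ≈ 1, so the variance component multiplying K is on the
  phenotypic-variance scale of standardized data.
* **GK (Gaussian)**: K_ii′ = exp(−h·d²_ii′/median(d²)), d² the squared
  Euclidean distance between marker rows, h = 1 by default.  The median is
  taken over the off-diagonal pairs i < i′ only; including the zero
  diagonal would deflate it.  The diagonal is exactly 1 and, with median
  scaling, half the off-diagonal entries sit above exp(−h) and half below.

Kernels are validated as symmetric (1e−10) and PSD up to round-off
(eigenvalues ≥ −1e−8·λ_max; smaller negatives are clipped to zero with a
warning where projection is requested).

## Model structures

With Z_E and Z_u the record→environment and record→line incidence matrices
(rows sum to 1; environments and lines ordered lexicographically for
reproducibility):

* SM (per environment): one random effect with covariance structure
  Z_u K Z_u′ and variance σ²_u.
* MM: the same structure across environments, variance σ²_u0.
* MDs: MM plus an interaction effect with structure
  [Z_u K Z_u′] ∘ [Z_E Z_E′] and a single variance σ²_ue.  The Hadamard
  factor Z_E Z_E′ zeroes all cross-environment entries, so the structure is
  (up to record ordering) block-diagonal in the per-environment kernels
  K_j.
* MDe: MM plus one component per environment, each the K_j block embedded
  at environment j's records with its own variance σ²_uE_j.  The blocks
  sum exactly to the MDs structure — the identity the tests check — so MDe
  with all interaction variances equal is MDs.

Fixed effects are an intercept for SM and an intercept plus (s−1)
treatment-coded environment contrasts for multi-environment models.  This
is one full-rank resolution of the overparameterized "grand mean + one
mean per environment" formulation; predictions and random-effect posteriors
are invariant to the choice, so nothing downstream depends on it.

Phenotypes are standardized by the overall across-environment mean and
sample SD before fitting.  In cross-validation the constants come from the
training records only, so test values cannot leak into the fit; the
constants are stored for back-transformation.  On standardized data fitted
with GB kernels the variance components approximately partition the unit
phenotypic variance, which the tests assert as a sum in [0.7, 1.3].

## Gibbs sampler

Each structure matrix Ω_k is eigendecomposed once, Ω_k = B_k Λ_k B_k′,
keeping eigenvalues above 1e−10·λ_max, and the effect is reparameterized as
η_k = B_k b_k with b_kj ~ N(0, σ²_k λ_kj).  Because the bases are
orthonormal over the complete record set, all coefficient full conditionals
are diagonal and one sweep costs O(n·m_k) per component.

Updates per iteration:

1. fixed effects from their Gaussian full conditional under flat priors;
2. each component's coefficients b_k coordinate-wise (jointly, as the
   conditional is diagonal);
3. each σ²_k from a scaled-inverse-χ² full conditional with df0 + m_k
   degrees of freedom and scale df0·S0_k + Σ_j b²_kj/λ_kj;
4. the residual σ²_ε likewise with df0 + n degrees of freedom;
5. phenotypes of masked (to-be-predicted) records redrawn from
   N(linear predictor, σ²_ε) — full data augmentation, so masked records
   participate in the complete-data conditionals and predictions are draws
   from the joint posterior and predictive distributions.  The augmented
   records therefore also enter the σ²_ε update (hence df0 + n with n the
   total record count): that is the exact full conditional of the
   augmented model.  Masked records are initialized at the training mean,
   and their stored phenotype values are never read.

Priors: every variance has a scaled-inverse-χ² prior with df0 = 5.  The
prior scale is set so the prior mode equals R²_k·Var(y_train)/mean(diag Ω_k),
with a total genetic R² of 0.5 split equally among the kernel components
and the remaining 0.5 assigned to the residual.  These are weakly
informative defaults of the kind standard Bayesian genomic-prediction
software uses; both df0 and the R² split are configurable on `ModelSpec`.

Chains: the default profile is 35,000 iterations with 5,000 burn-in and
thinning 5 (the full-scale analysis setting).  Cross-validation and tests
use `ModelSpec.reduced()` — 3,500/500/2 — because at the problem sizes used
here (hundreds of records) accuracy and posterior means are insensitive to
chain length, which the fixed-variance closed-form check quantifies
(max-abs error vs the exact mixed-model solution ≈ 0.01–0.02).  Identical
seeds give bit-identical chains; every consumer of randomness takes an
explicit seed, and per-partition CV seeds are derived deterministically
from the spec seed.

Posterior output: chains for every variance symbol and fixed-effect
coordinate; posterior mean and SD of the linear predictor per record (the
prediction contract for masked records); summaries with effective sample
size computed via arviz.

## Cross-validation

Partitions are organized as replicates × folds (default 10 × 5 = 50
partitions, 80% training).  Schemes:

* `within_env` — lines of one environment fold-split (used with SM);
* `CV1` — lines fold-split; a test line's records are masked in **all**
  environments (new-line prediction);
* `CV2` — records (line × environment cells) fold-split; a test line
  usually stays observed in other environments (sparse testing).  One
  published description of CV2 states that no test line appears in
  training, which contradicts the sparse-testing definition given
  alongside it; the package implements record-level masking, the standard
  sparse-testing reading.

Within a replicate, test sets are disjoint and cover the unit universe
exactly once (checked exhaustively in tests).  Every partition refits the
model from scratch on training data.  Accuracy is the within-environment
Pearson correlation between predictions and observed phenotypes; an
environment with fewer than 3 test records, or a zero-variance vector,
yields an undefined (NaN) correlation that is excluded from means and
counted, never zero-filled.  Percent change between two accuracies is
100·(new − base)/base rounded half away from zero — the rounding that
reproduces published accuracy-gain integers from two-decimal correlations.

Broad-sense heritability on plot means is provided as
σ²_h/[σ²_h + σ²_hs/s + σ²_e/(s·r)] over s environments and r replicates.

## Synthetic trial generator

The generator draws founder inbreds (per-marker allele frequency uniform
in `maf_range`, dosages 0/2), crosses random distinct parent pairs into F1
hybrids, and composes phenotypes from the models' own generative
assumptions: record value = β_Ej + u0_i + g_ij + ε_ij with u0 = Xα
(main marker effects), g_ij = Xα_j independent per environment (G×E
deviations; optionally per-environment variances), and i.i.d. residuals.
Every component is centered and rescaled so its realized sample variance
equals its target exactly — not just in expectation — giving recovery tests
sharp truth values.  With `epistasis_fraction` > 0, that share of each
genetic component's variance is routed through pairwise marker products
(p/2 random disjoint pairs), the non-additive architecture on which the
Gaussian kernel has an advantage.  Sparsity deletes a uniform random
fraction of cells while keeping every line in ≥1 environment and every
environment with ≥2 lines.

Default study conditions: 40 founders, 200 hybrids, 1,000 markers, 4
environments with means spread over [−0.5, 0.5], σ²_u0 = 0.4, σ²_ue = 0.2,
σ²_ε = 0.4, 70% of cells observed.  The environment-mean spread adds ≈0.14
of between-environment variance, so after across-environment
standardization the recoverable components shrink by ≈12% (0.40 → ≈0.35
etc.) — visible in, and accounted for by, the ±0.15 recovery tolerance.

What the generator does **not** emulate: linkage disequilibrium and
realistic haplotype structure (markers are independent), selection and
pedigree dynamics, spatial field trends, block-structured (trial-design)
missingness, and heterogeneous residual variances across environments.
Passing tests therefore demonstrate correctness of the estimation and
validation machinery under the models' own assumptions, not performance on
real field data.

## Scenario choices in the pattern tests

Conditions for the qualitative comparisons were fixed once, as realistic
mid-heritability hybrid-trial settings, and the problem sizes keep a full
test run at desk scale:

* Strong G×E: default trial with σ²_u0 = 0.2, σ²_ue = 0.4 (interaction
  twice the main variance), CV2 with 10 partitions — MDs-GB should beat
  MM-GB in every environment.
* Epistatic vs additive: 150 hybrids from 30 founders, 400 markers, 3
  environments, σ²_u0 = 0.5, σ²_ue = 0.2, σ²_ε = 0.3, 75% observed;
  `epistasis_fraction` 0.6 vs 0.0; MM fitted with both kernels over 5
  partitions × 5 seeds.  GK should win under epistasis and tie (mean
  |difference| ≤ 0.05) under additivity.
* CV2 vs CV1: 80 hybrids from 60 founders — a deliberately weakly related
  panel.  With a narrow founder base the kernel predicts held-out lines
  almost as well as their own records and the CV1/CV2 gap drowns in Monte
  Carlo noise; weak relatedness realizes the premise of the comparison
  (own-environment records add information the kernel cannot supply).

## Numerical choices and degenerate inputs

* Standardization tolerances: column means within 1e−8 of 0, SDs within
  1e−8 of 1; kernel symmetry 1e−10; PSD acceptance −1e−8·λ_max; eigenvalue
  truncation 1e−10·λ_max.
* All-identical marker rows make the Gaussian kernel's median zero →
  explicit error.  All-missing marker columns cannot be imputed → error
  (the call-rate filter removes them first).  Zero phenotype SD → error.
* Text output uses %.17g so file round trips are bit-identical for
  float64; readers use round-trip float parsing.
* A fold that would leave an environment without training records raises
  at plan construction rather than failing inside a fit.

## Limitations

Single-trait models only; no environmental covariates or unstructured
environment covariance; no REML/EM alternative to MCMC; convergence
monitoring limited to effective sample size; bandwidth of the Gaussian
kernel is fixed (median-scaled h = 1) rather than estimated.
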