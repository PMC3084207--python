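# Methods

This note documents the statistical models, the simulator that provides
their test bed, the numerical choices, and the limits of what the tests
demonstrate.

## Data model and adjustment

All genomic models act on adjusted phenotypes. Raw height is first
restricted to adults (age ≥ 18) and regressed by OLS on a male indicator
and a linear age term; the residual is the adjusted height `y_i`. A
constant sex or age column is dropped from the design rather than fitted
(recorded on the returned `AdjustmentModel`). Only a linear age term is
used; quadratic age or age×sex interactions are deliberately out of scope,
since nothing downstream depends on the adjustment beyond removing the
linear signal.

Genotypes are biallelic allele counts in {0, 1, 2} with an explicit
missing code. QC order is: call-rate filter (default ≥ 0.90), MAF filter
on non-missing calls (default ≥ 0.03, minor-allele oriented), then
imputation of surviving missing calls by sampling Binomial(2, p̂_l) under
Hardy–Weinberg proportions, with p̂_l the empirical counted-allele
frequency at marker l. Computing MAF before imputation means imputed
values can never influence the filters; a marker failing both screens is
tallied in both failure classes but removed once. Evenly spaced marker
panels are taken at indices ⌊j·p/n_target⌋, a deterministic convention
that makes panels reproducible without a genetic map.

## Genomic relationship matrices

Two constructions of the realized relationship matrix G are implemented,
with allele frequencies estimated from the same post-imputation sample
(there is no external reference panel in this setting):

* **Method Y** — off-diagonals are per-marker standardized
  cross-products, `G_ij = (1/p) Σ_l (x_il−2p_l)(x_jl−2p_l) / (2p_l(1−p_l))`;
  the diagonal uses the homozygosity-based estimator
  `1 + (1/p) Σ_l [x²_il − (1+2p_l)x_il + 2p²_l] / (2p_l(1−p_l))`.
* **Method H** — centered cross-products with one global scaling,
  `G = ZZ′ / (2 Σ_l p_l(1−p_l))`, `Z = X − 2p`.

Both are divided by their average diagonal so that it equals one; this
puts the additive variance parameter on the same scale whichever matrix is
used, and makes the two G's directly comparable. Both forms are verified
against element-wise loop oracles in the tests.

Method H is an exact Gram matrix and hence positive semi-definite to
rounding error. Method Y is not: its diagonal is estimated separately from
the cross-products, which leaves a small negative spectral mass (relative
magnitude ~1e−3 at 2,000 markers, larger at sparse panels). The GBLUP
sampler therefore projects negative eigenvalues to zero (the nearest-PSD
cone projection) and raises an error only when the negative mass exceeds
5% of the total spectral mass — a level never produced by genuine marker
data, only by corrupted inputs.

## Bayesian GBLUP

The model is `y = 1μ + g + e`, `g ~ N(0, σ²_g G)`, `e ~ N(0, σ²_e I)`,
with a flat prior on μ and scaled-inverse-χ² priors on both variances.
Defaults are df = 5 for both (finite prior mean and variance) and scales
set by the rule S = 0.5·Var(y)·(df−2)/df, i.e. both prior expectations
equal half the sample variance of adjusted phenotype — a weakly
informative symmetric starting point between "all genetic" and "all
residual".

Sampling uses the spectral reparameterization g = Uα with G = UDU′: the
α_j have independent normal full conditionals, so after one
eigendecomposition (reusable across chains and prediction) each Gibbs
cycle costs O(n). μ is drawn from its normal full conditional and each
variance from its scaled-inverse-χ² full conditional. Default chains are
30,000 iterations, 5,000 burn-in, thinning 5; analyses in the tests and
the acceptance script use shorter chains (2,500–20,000 iterations) chosen
to keep the full grids fast at desk scale — the eigenbasis updates mix
well and a split-chain diagnostic is available on every results object.
Correctness is gated on two oracles: with fixed variances the posterior
mean of g must match the closed-form mixed-model solve within Monte-Carlo
error, and GBLUP with G = XX′/k must reproduce the predictions of the
common-shrinkage marker sampler.

Heritability is summarized as the posterior mean of the per-draw ratio
σ²_g/(σ²_g+σ²_e) (not the ratio of posterior means). DIC uses the
conditional deviance D = −2 log N(y | μ+g, σ²_e I): Dbar is the mean over
kept draws, p_D = Dbar − D(posterior means), DIC = Dbar + p_D.

Out-of-sample prediction uses the mixed-model conditional mean at
posterior-mean variances, `ŷ_TST = μ̂ + G_TST,TRN (G_TRN + λI)^{-1}
(y_TRN − μ̂)` with λ = σ̂²_e/σ̂²_g. One G is built on all individuals and
each fold trains on its TRN sub-block; the (G_TRN + λI) form remains
well-defined when G_TRN is rank-deficient (marker count below n).

## Bayesian LASSO

The Park–Casella hierarchy: `β_l | τ²_l ~ N(0, τ²_l σ²_e)`,
`τ²_l ~ Exp(λ²/2)`, `λ² ~ Gamma(shape, rate)`, σ²_e scaled-inverse-χ²
with the same half-sample-variance rule. Marginally the β_l are
double-exponential, giving marker-specific shrinkage. Defaults for the λ²
prior are shape 0.55, rate 1e−4 (coefficient of variation ≈ 1.35, enforced
≥ 1 at construction), i.e. relatively flat over a wide range; λ² is
sampled, never tuned. The Gibbs cycle updates each β_l from its scalar
normal full conditional with residuals maintained in place (a
numba-compiled sweep, O(np) per cycle), 1/τ²_l from inverse-Gaussian full
conditionals, λ² from its Gamma full conditional, and σ²_e from a
scaled-inverse-χ² that includes the β′D⁻¹β term. Two degenerate modes
support testing and comparison: frozen common τ² (posterior mean of β then
targets the closed-form ridge solution) and a sampled common variance
(`shrinkage="common"`), the homogeneous-shrinkage marker model equivalent
to GBLUP with G = XX′/k.

No heritability is derived from this model: mapping marker effects and
allele frequencies to a genetic variance assumes linkage equilibrium,
which family data violate. Predictions use the training-panel marker ids
and centering constants; any panel mismatch is a hard error.

## The cohort simulator

The generator emulates the structure the analysis assumes: a founder
cohort paired into couples, an offspring cohort produced by Mendelian gene
dropping at unlinked biallelic SNPs, and an additive infinitesimal trait.
Defaults describe an adult-height-like trait: mean 167.4 cm, SD 9.5 cm,
h² = 0.8, a 13 cm male–female difference (typical adult sexual
dimorphism; the analysis only requires that a sex effect exist to be
removed), a −0.05 cm/year age slope, ages uniform on [18, 80] and
independent of genotype, and founder MAFs uniform on [0.05, 0.5].

Marker effects are i.i.d. normal with variance σ²_g / (2 Σ_l p_l(1−p_l)),
which gives E[Var(g)] = σ²_g = h²·SD² under Hardy–Weinberg proportions;
genetic values use centered genotypes so g has mean ≈ 0. Residuals are
i.i.d. normal with variance (1−h²)·SD². The realized heritability
converges to the target (verified within ±0.05 at n = 5,000, p = 2,000).

Family structure: offspring are assigned uniformly at random to eligible
matings, producing variable sibship sizes; a `half_sib_fraction` of males
also mate with the neighbouring couple's female (half-sib families), and a
`childless_fraction` of couples is excluded from mating so the cohort
contains individuals with no close relatives — without this, k-fold
testing would leave the s=0 stratum empty, unlike real cohorts where it is
the largest group. An odd founder count is allowed (the leftover founder
joins an existing couple's member). For QC testing, a configurable number
of markers is planted at MAF below the 3% screen and per-marker
missingness rates are drawn from a configurable range; phenotypes are
always computed from the pre-missingness genotype copy, which is retained
as an oracle (`true_genetic_value`).

What the simulator does **not** emulate: linkage disequilibrium (markers
are unlinked — the models never use map positions, and marker-density
effects are explored by subsetting), mutation, selection, assortative
mating, population structure or admixture, genotyping error beyond
missingness, and pedigrees deeper than two generations. Passing tests
therefore demonstrate correctness of the machinery and the
family-relatedness phenomena, not the LD-driven component of real-data
prediction accuracy (in real cohorts, part of R²_VAL for unrelated pairs
comes from population-level LD between markers and causal loci, which this
generator cannot produce; its s=0 accuracy derives from realized genetic
relationships at the causal markers themselves).

## Validation designs and relatedness stratification

k-fold CV assigns individuals to folds at random (fold sizes within one);
the two-generation design trains on the founder cohort and tests all
offspring (a single replicate by construction); the random-split design
draws replicate TRN sets of exactly the founder-cohort size, isolating
training-set composition from training-set size. Leakage (TRN∩TST ≠ ∅) is
a hard error wherever ids are available.

The relatedness score of a tested individual sums 1 for each parent,
offspring, or full sib in the training set and 0.5 for each half sib;
grandparental and avuncular pairs score 0. Strata are s=0, s=1, s=2, s≥3,
with fractional scores rounded down (a lone half sib lands in s=0). These
cut points and the rounding rule are a documented interpretation — the
narrative this follows describes exactly four integer-indexed groups — and
both are configurable. Stratified R²_VAL is computed after pooling test
predictions across folds. The scoring operation is verified against an
exhaustive pair-loop oracle on random pedigrees.

`run_experiment` executes the grid (models × marker counts × designs),
reports replicate means and the coefficient of variation of R²_VAL, and
flags negative R²_VAL values rather than clamping them.

## Numerical and design choices

* Missing genotypes are encoded as −1 in an int8 matrix; containers
  validate entries, id alignment, and pedigree acyclicity on
  construction.
* Scaled-inverse-χ²(ν, S) draws are νS/χ²_ν; inverse-Gaussian draws use
  the generator's Wald sampler with the mean capped at 1e8 (β ≈ 0 guard).
* The within-fold GBLUP seed is derived deterministically from the
  experiment seed and fold index; all simulation streams derive from the
  config seed via independent substreams, so cohorts are bit-reproducible.
* The acceptance script's cohort (900 individuals, 2,000 markers, three
  marker densities, 5-fold CV, three designs) is sized to make every
  qualitative contrast (marker-density gain, relatedness gradient,
  train/validation gap) clearly resolvable at desk scale on one CPU.

## Known limitations

* GBLUP prediction uses posterior-mean variances in the conditional-mean
  predictor rather than averaging the conditional mean over variance
  draws; at the chain lengths used the difference is well below replicate
  noise.
* The Bayesian LASSO reports no genetic variance, so DIC is its only
  model-comparison output.
* The simulator's two-generation limit means avuncular/grandparental
  relationships never occur, so the score's zero-weighting of those
  classes is untested against data that contain them.
* Naive Monte-Carlo standard errors ignore autocorrelation; the
  split-chain diagnostic is provided for checking mixing, but effective
  sample sizes are not computed.
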