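# Methods

This note documents the statistical models implemented in `hybridgs`, the
defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
more than one reasonable implementation existed.

## Study design and data model

The package targets an NC II (North Carolina II) factorial: every inbred
female line is mated to every male-sterile tester, giving
`n_females × n_males` F1 hybrids.  Because the parents are (effectively)
fully homozygous, each hybrid's genotype is determined by its parents:
like homozygotes breed true, opposite homozygotes give a heterozygote.
`crossing.deduce_hybrid_genotypes` computes the hybrid code as the mean of
the two parental codes; residual parental heterozygosity yields expected
dosages of ±0.5, which are flagged and accepted by all downstream models
(an additive model is unbiased under expected dosage).  Reciprocal crosses
are treated as identical — maternal and cytoplasmic effects are out of
scope.

Genotypes are coded −1/0/+1 for minor-allele homozygote, heterozygote and
major-allele homozygote.  The kinship and the Bayesian samplers use these
raw codes; LASSO, PLS and SVR standardise marker columns internally and
back-transform effects, since their penalties/kernels are scale-sensitive.

### Genotype QC and encoding choices

* Missing-rate filtering is per group (e.g. testers vs lines) with
  *strict* thresholds: a marker is removed only when its missing fraction
  in some constrained group exceeds that group's threshold.
* Missing calls surviving QC are imputed to the per-marker mode of the
  observed codes, ties going to the heterozygote.  The rule is
  deterministic, keeps the integer coding intact for exact hybrid
  deduction, and is adequate at the low missing rates QC leaves behind; it
  ignores linkage information by design.
* Minor/major orientation is recomputed from the observed allele
  frequency; a 50/50 tie is broken lexicographically (the smaller allele
  string is treated as major) so that encodings are reproducible.  When a
  marker is re-oriented its stored ref/alt metadata are swapped too, so
  +1 always maps to ref/ref on write and file round-trips are exact.
* Marker-set intersection matches on (chromosome, position) and accepts
  alleles as written or as a ref/alt swap (codes negated).  No strand
  flipping is attempted; A/T and C/G swaps are negated like any other swap
  but logged, since they are unresolvable without strand information.

## GBLUP and profiled REML

Model: `y = Xβ + g + ε`, `g ~ N(0, K φ²)`, `ε ~ N(0, I σ²)`, with
`K = (1/m) Z Zᵀ` — deliberately *not* centred and with no
allele-frequency denominator, so that the relationship form is exactly
equivalent to ridge regression on the raw codes.  `X` is an intercept
only (`q = 1`): environments are averaged into one record per hybrid
before modelling and no other fixed effects are defined.

`β` and `σ²` are profiled out analytically
(`β̂ = (XᵀH⁻¹X)⁻¹XᵀH⁻¹y`, `σ̂² = (y−Xβ̂)ᵀH⁻¹(y−Xβ̂)/(n−q)`,
`H = Kλ + I`), leaving a 1-D problem in `λ`.  Numerics:

* One eigendecomposition `K = U D Uᵀ` per fit; every likelihood and
  gradient evaluation is then O(n), which matters because replicated CV
  and subsampling refit the model thousands of times.
* Optimisation in `θ = log λ` on `[−6·ln10, +6·ln10]` (λ from 1e−6 to
  1e6).  A 49-point scan brackets a sign change of the analytic gradient
  dL/dθ; safeguarded Newton steps (finite-difference curvature of the
  analytic gradient) are taken only while they stay inside the bracket,
  otherwise the step falls back to bisection.  Convergence at
  |Δθ| < 1e−8, maximum 100 iterations.  The property tests require the
  optimum to match a 2,000-point log-grid search, which the safeguarding
  guarantees.
* A maximum on the lower boundary is reported as `λ̂ = 0` (pure-noise
  phenotype), not as an error.  Eigenvalues of `K` above −1e−8 are clipped
  to zero; anything more negative is a hard error.

Prediction uses the relationship identity
`ŷ = X_testβ̂ + λ̂ K_cross (λ̂K_train + I)⁻¹ (y − Xβ̂)`; the residual solve
is cached at fit time.

## The other five learners

* **LASSO** — coordinate descent on a log-spaced penalty path
  (scikit-learn), penalty chosen by minimum 5-fold CV MSE (the min-CV
  rule, not 1-SE).
* **BayesB** — own Gibbs sampler.  Effect `γ_k` is zero with probability
  π and otherwise `N(0, σ²_k)`, `σ²_k ~ scaled-inv-χ²(v = 4.234,
  S = 0.0429)`.  Indicators are updated from the likelihood with `γ_k`
  integrated out (collapsed update; naive joint updates mix poorly).
  π gets a Beta prior parameterised by mean 0.5 and concentration 10
  (shape a = 0.5·10, b = 0.5·10); the residual variance gets a
  Jeffreys-type scaled-inv-χ² update.  Chain defaults
  12,000/2,000/5 (iterations/burn-in/thin) are configurable; the test
  suite and acceptance script run shorter chains (3,000/800/4) that
  already pass the recovery diagnostics.  A fixed seed makes chains
  bit-reproducible.  Note that the slab scale S is fixed on the
  squared-phenotype scale: for traits whose residual variance is large
  relative to S the inclusion indicators are weakly identified and sit
  near their prior (the null-data diagnostic exploits exactly this),
  while on variance-1 data the Occam factor actively switches markers
  off.
* **PLS** — PLS1 (scikit-learn), component count by minimum 5-fold CV
  RMSE over 1..max_components (default max 10).
* **SVR** — ε-insensitive support vector regression with the Gaussian
  kernel `exp(−‖z_i−z_j‖²/(2h²))`; defaults C = 1, ε = 0.1·sd(y), and the
  median pairwise-distance heuristic for h.  No grid search by default.
* **RKHS** — own Gibbs sampler for `y = μ + Σ_l u_l + ε`,
  `u_l ~ N(0, σ²_l K_l)`, with Gaussian kernels at squared bandwidths
  `multiplier × mean squared pairwise distance`, default multipliers
  {0.2, 1, 5} (kernel averaging across a coarse bandwidth grid).  Sampling
  is done in each kernel's eigenbasis; variance components get weakly
  informative scaled-inv-χ² priors (df 5, prior mode at half the
  phenotypic variance, split across kernels).  Passing `fixed_ratios`
  replaces sampling by the closed-form posterior mean, which the tests
  use as an exact oracle.  Predictions extend to new genotypes through
  the kernel cross-block applied to `α_l = K_l⁺ u_l`.

All six satisfy one contract: fit on an encoded genotype matrix and a
phenotype vector, predict any matrix over the same markers.

## Evaluation

* **Cross-validation.**  Balanced random k-fold partition per replicate
  (fold sizes differ by at most one); every sample is predicted exactly
  once per replicate and a single Pearson correlation is computed over
  the pooled out-of-fold predictions.  The per-fold-correlation
  alternative was rejected: pooling matches the "each part predicted
  once" protocol and gives one well-defined r per replicate.  Defaults
  k = 5, 20 replicates.
* **ANOVA.**  Two-way fixed-effects factorial (trait, method,
  interaction) on the balanced replicate table, closed-form sums of
  squares; an 8×6×20 layout gives df (7, 5, 35, 912).
* **Multiple comparisons.**  Tukey HSD at α = 0.05 on the factor-level
  means using the ANOVA residual MS, with letters assigned by the
  standard sorted-means sweep.  HSD was chosen because it is the
  conventional procedure behind letter-group displays.
* **Subsampling experiments.**  For each subset size, repeated uniform
  random subsets of markers or hybrids, each scored by one fivefold CV;
  reported as mean ± sd over selections.  Library defaults are
  desk-scale (marker sizes up to a few thousand, 20 selections); the
  counts are configurable upward.
* **Heritability.**  Expected-mean-squares estimators from the balanced
  genotype × environment × replicate ANOVA:
  `σ̂²_ε = MS_resid`, `σ̂²_ge = (MS_GE − MS_resid)/r`,
  `σ̂²_g = (MS_G − MS_GE)/(re)`, negatives clamped to zero, and
  `H = σ²_g/(σ²_g + σ²_ge/e + σ²_ε/(er))`.  Requires e ≥ 2 and r ≥ 2;
  unbalanced layouts are rejected rather than approximated.

## Selection

Cross ranking enumerates females × candidates, deduces hybrid genotypes
in streamed blocks of ≤ 10,000 so candidate panels of hundreds of
thousands of crosses fit in memory, and sorts predictions descending with
the hybrid id as a stable tie-break.  Top-k gain is
`mean(top k) − mean(all)`, absolute and as a percentage of the all-cross
mean; the all-cross mean includes every enumerated cross (training
combinations are not excluded).  The gain curve is the cumulative mean of
the sorted predictions, with a nonparametric bootstrap (default 1,000
resamples of the top-k set) for a 95% interval of the top-k mean — the
interval construction is this package's choice.  Method overlap reports
`|top-k(a) ∩ top-k(b)|` and the Pearson correlation of the full
prediction vectors aligned by hybrid id.

## Synthetic data generator

`simdata` emulates the statistical structure the pipeline assumes:

* **Parents** are fully homozygous; marker codes come from thresholding a
  latent AR(1) Gaussian, giving allele frequencies drawn uniformly from
  `maf_range` (default 0.05–0.5) and first-order LD with neighbour
  correlation `ld_rho` (default 0.2 — enough short-range structure that
  marker subsets tag each other without modelling real LD decay).
* **Defaults** mirror the emulated design: 115 female lines, 5 testers
  (575 training hybrids), 2,000 markers, and a 200-accession candidate
  panel as a computational stand-in for a 3,023-accession germplasm
  collection.
* **Traits.**  Eight default architectures with broad-sense
  heritabilities 0.3031 (GY), 0.8501 (TGW), 0.2550 (PN), 0.7501 (PH),
  0.6676 (SB), 0.6262 (GN), 0.7802 (PL), 0.6944 (PB), 50 normal-effect
  QTL each, and field-plausible trait means so relative gains are on a
  realistic scale.  A mixture option concentrates most genetic variance
  in a few major QTL for sparse-model diagnostics.
* **Phenotypes.**  `y_ijl = μ + g_i + ge_ij + ε_ijl` over e = 2
  environments × r = 2 replicates.  The genetic values are rescaled to
  variance exactly 1, and the noise variances are set so the
  genotype-mean heritability hits the target exactly:
  `σ²_ge/e + σ²_ε/(er) = (1−H)/H`, split 50/50 between interaction and
  residual (only H is specified by the emulated design; the split is a
  package default and configurable).
* **Not emulated:** population structure, realistic LD decay, selection,
  dominance/epistasis (a dominance knob exists but defaults to 0), trait
  correlations, unbalanced field layouts, genotyping error.  Passing
  tests on these data therefore demonstrate correctness of the machinery
  and the qualitative heritability/marker/size behaviour, not calibrated
  real-data predictabilities.

## Randomness policy

A master seed spawns independent named streams (folds, fits, subsets,
chains, simulation panels) via `SeedSequence`, so each experiment is
individually reproducible and adding one experiment does not shift the
randomness of another.

## Problem sizes

The default test-suite and acceptance-script runs use a 575-hybrid bundle
with 1,000 markers, 5–20 CV replicates, 8 selections per subsampling
size, and 3,000-iteration Bayesian chains.  These sizes were chosen so
the full verification cycle completes in minutes on a single core while
every diagnostic (parameter recovery, ordering, plateau, sampler
behaviour) is already stable at them; all counts scale up through
configuration.

## Known limitations

* REML profiles a single variance ratio; additive + dominance
  two-component models and analytic (leave-one-out style) predictability
  approximations are not implemented.
* The heritability estimator requires balanced data.
* BayesB and RKHS chains are plain Python loops over markers/kernels —
  adequate at desk scale, slow for 10⁵+ markers.
* VCF writing targets coded biallelic SNP panels (GT only); fractional
  hybrid dosages must be stored in the TSV dialect.
* No multi-trait models, index selection, or diversity constraints on
  the selected cross set.
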