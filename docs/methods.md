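# Methods

## Model

`mtgibbs` fits the multi-trait pedigree animal model

    y = Xb + Zu + e,
    Var(u) = G ⊗ A,    Var(e) = R ⊗ I,

where `y` stacks the trait observations, `b` holds trait-specific fixed
effects (contemporary-group factors such as batch–sex–technician or
slaughter date, plus linear age covariates), `u` holds one additive-genetic
effect per animal and trait, `A` is the pedigree numerator relationship
matrix, and `G` and `R` are the k×k additive-genetic and residual
covariance matrices.  The reported quantities are posterior means and SDs
of the per-trait variances, heritabilities h² = G_ii/(G_ii + R_ii), genetic
correlations r_g = G_ij/√(G_ii G_jj), and phenotypic correlations
r_p = (G_ij + R_ij)/√(σp²_i σp²_j), each computed per retained sample and
then averaged (ratio-then-average; averaging components first can differ in
the second decimal).

Assumptions: a single record per animal and trait; no maternal,
permanent-environment or litter effects; composite contemporary groups are
supplied pre-combined; covariates enter linearly and are centred at their
observed mean (centring constants are retained so predictions are
recoverable); marbling score (a 1–9 grade) is treated as a continuous
response, matching the linear model this pipeline reproduces; no explicit
identifiability constraint is imposed on fixed effects — with flat priors
the variance components and estimable functions remain well defined, but
individual factor-level solutions are not identified and should not be
interpreted.

## Pedigree algebra

Pedigrees are topologically ordered at load time (ties broken by input
order, so renumbering is deterministic); parents referenced but never
listed are appended as founders.  Inbreeding coefficients use the
Meuwissen & Luo ancestor-decomposition recursion; `A⁻¹` is assembled
directly by Henderson's rules with Mendelian-sampling variances
d_i = 0.5 − 0.25(F_s + F_d) (0.75 − 0.25 F_p for one known parent, 1 for
none).  Unknown parents are unrelated, non-inbred base individuals;
unknown-parent groups are not implemented.  Inbreeding can be switched off
(`use_inbreeding=False`) to mimic software that ignores it.  A dense `A`
(tabular method) exists for testing and refuses pedigrees above 2,000
animals; the sampler itself only ever touches the sparse `A⁻¹`.

## Gibbs sampler

One iteration scans:

1. **Location effects.**  Fixed-effect coefficients are updated single-site
   (Gauss–Seidel style); breeding values are updated as per-animal blocks
   across all k traits, whose full conditionals couple parents, progeny and
   mates through `A⁻¹ ⊗ G⁻¹`.  Residuals are maintained incrementally, so
   no design-matrix products are formed.  The scan is jit-compiled
   (numba); innovations are pre-drawn from a dedicated stream.
2. **Missing-trait augmentation.**  For each missingness pattern, missing
   residuals are drawn from their conditional normal given the observed
   residuals under the current `R`.  The complete-data model gives missing
   cells the mean `u_it` (no fixed-effect terms), so `X` spans observed
   cells only; marginalising the imputed cells leaves the observed-data
   posterior unchanged while keeping all conditionals conjugate.
3. **Covariances.**  `G | u ~ IW(U'A⁻¹U + S0_G, q + ν0_G)` over all q
   pedigree animals (recorded or not), and `R | e ~ IW(E'E + S0_R, n + ν0_R)`
   over the n animals with at least one record.  Draws failing a Cholesky
   check are jittered once (1e-8 × trace) and abort if still indefinite.

All randomness derives from one root seed through four independent
`SeedSequence` streams (location, augmentation, G, R), so runs are exactly
reproducible and toggling storage options cannot perturb the (G, R) stream.
Chains are initialised at b = 0, u = 0 and a half-additive/half-residual
split of the observed per-trait variance.

### Prior convention and the flat-prior hazard

The default is the "flat" convention S0 = 0, ν0 = 0 (posterior df q and n),
equivalent to the improper prior |Σ|^{−(k+1)/2} on each covariance matrix;
ν0 = −(k+1) gives the alternative uniform-density convention, and both are
configurable.  With records on only a minority of pedigree animals, either
improper convention admits a degenerate boundary region: `R` can drift
toward singularity in one trait combination while breeding values absorb
the corresponding residuals exactly and `G` inflates, which manifests as a
self-reinforcing excursion the chain cannot leave (a posterior-propriety
hazard of improper covariance priors in hierarchical models).  The remedy
is a weakly informative proper scale, `stabilizing_scale(design, factor)`,
giving S0 = factor × diag(observed phenotypic variance) with ν0 = 0.  The
barrier term tr(S0 R⁻¹) grows without bound as R degenerates while adding
only `factor` records' worth of information.  Recommended factors: 1e-3
for datasets of a few hundred records or more (used by the recovery entry
points; on well-behaved replicates it changes the estimates by less than
Monte-Carlo error), a few percent (0.05) for very small datasets of order
100 animals, where the flat posterior itself is badly behaved.  The
sampler's defaults remain exactly flat.

### Schedule

The production schedule is 550,000 cycles, 50,000 burn-in, thinning 50
(10,000 retained samples).  Tests and the acceptance script use reduced
chains (25,000 / 5,000 / 10 at ~2,000–3,000 animals, which run in a few
tens of seconds each); the package's recovery experiments showed these are
long enough for posterior means and SDs of h² and r_g at that data size.

## Diagnostics

Effective sample size uses the arviz autocorrelation-time estimator; the
Geweke z compares the means of the first 10% and last 50% of a stream with
spectral-density-at-zero variance estimates (lag window √m, Bartlett
weights), flagging |z| > 2.  Streams shorter than 50 retained samples skip
diagnostics with a warning; constant streams are flagged as degenerate
rather than crashing.  Trace plots for σa², σe² and h² per trait are
exported as PNGs.

## Synthetic data generator

The generator emulates a Korean beef-cattle (Hanwoo) performance/progeny
testing structure: discrete generations, random mating without selfing,
every non-founder with two known parents.  Breeding values follow the
pedigree exactly: founders ~ MVN(0, G), offspring are parent averages plus
Mendelian deviations MVN(0, (0.5 − 0.25(F_s + F_d)) G).  Residuals are
i.i.d. MVN(0, R) per animal.  Fixed effects are contemporary-group draws
N(0, τ²) per level plus a linear age covariate, with τ² set so all fixed
terms jointly contribute 20% of a trait's phenotypic variance (effect sizes
are not published for the study data; 20% is a realistic, non-degenerate
choice).  Yearling weight can be emitted as two raw weights and weighing
days (drawn uniformly in [150, 250] and [330, 420]) consistent with the
simulated trait, exercising the projection formula end to end.

The default 8-trait parameter set (`hanwoo_design`) uses the published
posterior means for all variances and correlations (ultrasound
intramuscular fat/eye-muscle area/backfat; carcass backfat, weight,
eye-muscle area, marbling; yearling weight).  Because those values are
printed to two decimals, the assembled 8×8 genetic covariance has one
slightly negative eigenvalue (−4e−4); it is clipped to a small positive
floor.  Missingness classes mirror the published record counts: scanned
and unscanned steers and bulls, with carcass traits on steers only,
ultrasound on the scanned subset and yearling weight on everyone.  Founders
are never recorded.  The 3-trait `recovery_design` (carcass weight,
eye-muscle area, marbling score; steer fraction 5622/15796) is the standard
recovery benchmark; its covariance matrices are positive definite as
printed.

Default scale is ~2,000 animals so recovery experiments run in minutes;
`hanwoo_design(scale=8)` approaches the study's record counts.  What the
generator does **not** emulate: selection and assortative mating,
generation overlap, genotype data, non-random missingness within a class,
age structure in contemporary groups, and data-editing artefacts.  Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated model, not robustness to real-data violations of it.

## Numerical choices

- Factor levels are coded lexicographically; missing values are an explicit
  boolean mask, never a sentinel.
- Factor levels with no observed record for their trait are dropped;
  single-level factors are kept but flagged (they act as intercepts).
- Missingness patterns are ordered by member count, ties by the mask read
  as a binary number (descending) — deterministic across runs.
- Repeated records per animal are rejected (no permanent-environment
  effect is fitted).
- `A⁻¹·A = I` holds to 1e−8 on random pedigrees up to 200 animals (tested);
  the dense tabular `A` is PSD to −1e−10.
- Animals with no observed traits stay in the pedigree (their u is sampled
  from its prior conditional) and never enter R's scale matrix.

## Known limitations

- Threshold (categorical) models for marbling score are not implemented;
  the linear treatment matches the reproduced analysis but is statistically
  questionable for a 1–9 grade.
- No REML/EM estimators, no multiple chains in one process (replicates are
  run by seed), no unknown-parent groups, no genomic relationships.
- With the exactly-flat prior and sparse recording, the boundary hazard
  described above means long production chains should be monitored (trace
  plots, Geweke flags); the stabilized prior is recommended whenever
  records cover a minority of the pedigree.
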