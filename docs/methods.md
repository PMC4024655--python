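# Methods

## The problem

Genomic prediction estimates an animal's additive genetic merit (its
breeding value) from genome-wide SNP genotypes, using a training set of
genotyped and phenotyped animals. When several populations (breeds) are
available, two naive strategies bracket the design space: fit each
population separately (*single-task*), which wastes the other populations'
information, or stack everything into one training set (*pooling*), which
wrongly assumes identical SNP effects everywhere. The multi-task model
implemented here sits between the two: populations share **which** markers
carry signal, but not **how much** signal each carries.

## Models

All three models are spike-and-slab whole-genome regressions fitted by
Gibbs sampling. For population k (k = 1..c), sample i and marker j:

    y_ik = mu_k + sum_j x_ijk a_jk + e_ik,     e_ik ~ N(0, sigma2_ek)

with x coded 0/1/2 (copies of an arbitrary reference allele). Each SNP
effect has a two-component mixture prior governed by a latent indicator
gamma_j shared across populations:

    a_jk | gamma_j, sigma2_ak ~ gamma_j N(0, sigma2_ak) + (1 - gamma_j) delta_0
    gamma_j | w ~ Bernoulli(1 - w),   w ~ Uniform(0, 1)
    sigma2_ak ~ ScaledInvChi2(v_a, s2_a),  sigma2_ek ~ ScaledInvChi2(v_e, s2_e)

* **Single-task** is the c = 1 case (a BayesC-pi-style prior with estimated
  exclusion probability w).
* **Pooled** stacks all populations with population origin as a fixed
  effect (per-population intercepts mu_k) and one shared effect vector,
  slab variance and residual variance.
* **Multi-task** keeps per-population effects a_jk, intercepts and
  variances, but a single gamma vector. The indicator update multiplies
  the marginal-likelihood ratios of all populations, which is the only —
  and deliberately weak — channel of information sharing: the model does
  not use the between-population effect correlation explicitly.

## Gibbs sampler

A systematic-scan chain with joint (gamma_j, a_j.) updates:

1. gamma_j ~ Bernoulli(1/(1 + q_j)), where in log space

       log q_j = log w - log(1-w)
               + sum_k [ 1/2 log(x'x sigma2_ak / sigma2_ek + 1)
                         - 1/2 mu_hat_jk^2 / s2_hat_jk ],
       mu_hat_jk = x' y*_k / (x'x + sigma2_ek / sigma2_ak),
       s2_hat_jk = sigma2_ek / (x'x + sigma2_ek / sigma2_ak),

   with x' y*_k recovered from the maintained residuals as
   x' e_k + x'x a_jk, so one sweep costs O(n m) (residual-update scheme).
2. a_jk = 0 for all k if gamma_j = 0, else a_jk ~ N(mu_hat_jk, s2_hat_jk)
   independently per population; residuals shifted by -x (a_new - a_old).
3. w ~ Beta(m - sum(gamma) + 1, sum(gamma) + 1) — the exact conditional
   under the uniform prior. A `w_posterior_form="as_printed"` mode draws
   Beta(m - sum(gamma), sum(gamma)) with parameters floored at 1e-8 and
   draws clipped into (0, 1); that parameterization is improper at the
   boundaries, which is why it is not the default.
4. sigma2_ak ~ ScaledInvChi2(v_a + sum(gamma),
   (v_a s2_a + sum_j gamma_j a_jk^2) / (v_a + sum(gamma))).
5. sigma2_ek ~ ScaledInvChi2(v_e + n_k, (v_e s2_e + e'e) / (v_e + n_k)).
6. mu_k ~ N(mu_k + mean(e_k), sigma2_ek / n_k); residuals shifted.

Initialization is the prior-mean start: gamma = 0, a = 0, w = 0.5,
mu_k = the population phenotype mean, variances at their prior means
s2 v/(v-2). Marker visit order is ascending index (a shuffle flag exists,
off by default, for experimentation); this keeps chains exactly
reproducible under a fixed seed.

Posterior summaries average **all** recorded post-burn-in draws, zeros
included, so `effect_mean` is the unconditional posterior mean and GEBV is
a plain dot product plus the population intercept mean.

### Numerics

* q_j is computed entirely in log space with a branch-stable logistic,
  because the determinant product overflows at large x'x/sigma2 ratios.
* The marker sweep is numba-compiled; the pure-Python conditional-update
  operations are the reference implementation and accumulate the x'e dot
  product sequentially so the two paths are bit-identical (BLAS summation
  order differs, and a one-ulp difference in an inclusion probability can
  flip a Bernoulli draw and decouple the chains).
* The chain aborts with a diagnostic if any variance leaves
  [1e-12, 1e12] or w leaves (0, 1).
* `validate_every = k` recomputes residuals from scratch every k sweeps
  and checks the maintained vector to a relative 1e-8, plus the spike
  constraint (gamma_j = 0 implies a_jk = 0); the experiment driver runs
  with per-sweep validation since the check is a cheap BLAS product.
* x'x = 0 (a monomorphic marker within a population) needs no special
  casing: the conditional mean is 0 and the variance equals the slab
  variance, and the marker's evidence term vanishes.

### Priors

Defaults v_a = 4, v_e = 10. Scales are anchored at known variances via the
scaled-inverse-chi-square mean, S2 = sigma2 (v - 2)/v: in simulation the
true (realized) per-population genetic and residual variances are used; on
real data REML estimates would take their place. The pooled model, which
estimates a single variance pair, receives training-size-weighted averages
of the per-population variances. Note the slab scale is anchored at the
*total* genetic variance, not a per-SNP share — this follows the source
convention and acts as a weakly informative prior; the sampler estimates
sigma2_ak from the data anyway.

## Synthetic data generator

The generator replaces proprietary dairy-cattle chip genotypes with a
parametric stand-in carrying the features the models are sensitive to:

* **Divergence**: ancestral frequencies Uniform(0.1, 0.9); per-population
  frequencies Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F), default
  F = 0.1 (moderate breed divergence).
* **LD**: each haplotype is a thresholded latent AR(1) Gaussian,
  z_j = phi z_{j-1} + sqrt(1-phi^2) eps, allele = 1 iff z_j < Phi^-1(p_jk);
  default phi = 0.95 gives neighbour genotype correlations of ~0.5-0.7,
  decaying geometrically. Genotype = sum of two independent haplotypes
  (Hardy-Weinberg within population).
* **MAF floor**: markers with realized MAF < 0.05 in either population are
  resampled with fresh LD-free columns until the panel passes, so
  generated panels need no MAF QC. (Regenerating the whole AR chain would
  disturb markers that already passed.)
* **QTL**: drawn uniformly from a low-density pool (every 8th marker, a
  "50k-like" subset of the dense panel); allele-substitution effects per
  population are bivariate normal with unit variances and correlation rho,
  constructed as alpha2 = rho alpha1 + sqrt(1-rho^2) z so rho = 1 gives
  exact equality.
* **Trait**: TBV_i = sum_j X_ij alpha_jk exactly; genetic variance per
  population is the linkage-equilibrium sum 2 p (1-p) alpha^2 over
  *realized* QTL frequencies; sigma2_e = sigma2_a (1-h2)/h2, so at the
  default h2 = 0.5 residual and genetic variances are equal by
  construction. Under LD, var(TBV) can deviate from this sum; the formula
  defines the heritability target, which is the source convention.
* **Panels**: optional thinning (every 2nd/4th/8th marker, anchored at
  index 0), QTL columns removed by default or retained on request
  (appended if thinning dropped them).
* **Split**: seeded random train/validation split per population
  (defaults 393/65 and 2,084/214 of 458 and 2,298), replacing the
  birth-year split used with pedigreed real data.

What the generator does **not** emulate: empirical LD structure of real
chips (block structure, MAF-dependent LD), mutation/drift genealogy,
genotyping or imputation error, non-additive effects, and selection. Tests
passing on this generator show the samplers recover the model they assume
under realistic divergence and LD scales — not that accuracies match any
particular real-data value.

## Evaluation

GEBV for a validation animal is the population intercept mean plus the dot
product of its panel genotypes with the posterior-mean effects (the shared
column for pooled fits). Accuracy is the Pearson correlation r(GEBV, TBV);
bias is the slope b(TBV, GEBV) = cov(TBV, GEBV)/var(GEBV), with b < 1
indicating inflated (over-dispersed) GEBV. Scenario cells are replicated
with deterministic per-replicate seeds and summarized as mean +/- standard
error over replicates.

## Desk-scale study configuration

The full-scale study (246,668 SNPs, 50,000 cycles) is configurable but the
default experiment runs a desk-scale analogue chosen for a single CPU:
2,000 markers, small population 520 (400 train / 120 validation), large
population 1,400 (1,200 / 200, keeping roughly the 3:1 training imbalance),
chains of 5,000 cycles with 1,000 burn-in, 5 replicates. At this scale the
qualitative pattern — multi-task helping the small population most when
QTL effects are highly correlated and QTL genotypes are in the panel, and
naive pooling hurting accuracy and inflating GEBV when effects are weakly
correlated — reproduces; exact full-scale accuracies do not transfer and
are not asserted.

## Known limitations

* The near-duplicate QC scan is windowed (default 100 adjacent markers)
  rather than all-pairs; all-pairs mode exists but is quadratic.
* Missing genotypes entering a sampler are mean-imputed within population;
  no LD-aware imputation.
* The pooled model uses one residual variance for the stacked data.
* No convergence diagnostics beyond the optional trace; burn-in is a
  configuration choice.
* Indicator-based sharing ignores the magnitude correlation of effects, so
  with many small, highly correlated QTL the pooled model can outperform
  the multi-task model — a property of the model, not the implementation.
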