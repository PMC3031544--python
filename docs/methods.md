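# Methods

## The model

`latentpop` clusters `N` diploid individuals genotyped at `L` codominant
loci into `K` genetic clusters while simultaneously regressing the latent
cluster labels on per-individual covariates (geographic coordinates,
linguistic factors).

**Genotype layer.** Given the label `z_i`, the two allele copies at every
locus are independent draws from the cluster's allele-frequency vector
(no-admixture likelihood).  Frequency rows carry independent
Dirichlet(`lambda`) priors, `lambda = 1` by default (uniform; configurable).
Copies coded `-9` in input are treated as missing and skipped in both the
likelihood and the count statistics.

**Label layer (hidden multinomial probit).** Each individual carries K
latent Gaussian utilities

    y_ik = x_i' beta_k + eps_ik,   eps_ik ~ N(0, 1)  iid,

and `z_i = argmax_k y_ik`.  One cluster is the *reference* with
`beta_ref = 0`, so that with all coefficients zero membership is uniform
and the remaining K-1 coefficient vectors are identified.  The induced
membership probabilities are

    pi_k(x) = ∫ phi(u - x'beta_k) prod_{j≠k} Phi(u - x'beta_j) du.

**Design matrix.** An intercept column first; geographic trend surfaces are
linear (lat, long) or quadratic (plus lat², long², lat·long); continuous
covariates are centered and scaled to unit standard deviation *before*
polynomial expansion (conditioning of D'D; raw coordinate scales are
arbitrary).  Factors are effects-coded: a factor with m observed levels
(sorted) contributes m-1 columns and the last level's rows are -1, which
encodes the sum-to-zero identifiability constraint directly.

**Coefficient prior.** `beta_k ~ N(0, prior_sd² I)` with `prior_sd = 10`
(weakly informative on standardized covariates).  A fully flat prior is
tempting but makes the joint posterior *improper*: the marginal prior
weight of a labeling with an empty cluster, `∫ prod_i pi_{z_i}(beta) dbeta`,
diverges (for K = 2, intercept only, it contains `∫ Phi(a/√2)^N da = ∞`).
With a proper Gaussian prior every quantity below is well defined; at
`prior_sd = 10` the prior is far wider than any fitted coefficient in the
benchmarks.  `update_beta` itself defaults to the flat-prior conjugate
update (posterior `N((D'D)^{-1}D'y_k, (D'D)^{-1})`), which is the textbook
limit; the sampler passes its Gaussian prior through as a ridge term.

## The sampler

One sweep of the Gibbs sampler:

1. **Frequencies** `P | Z, X`: Dirichlet(`lambda` + allele counts) per
   cluster × locus; empty clusters draw from the prior.
2. **Labels** `Z | beta, P, X`: utilities integrated out;
   `z_i ∝ exp(loglik_i(k)) · pi_k(x_i)`, normalized in log space.
3. **Scale move** (collapsed Metropolis): propose `beta -> c·beta` with
   `log c ~ N(0, 0.4²)`, accepted against `p(beta|Z) ∝ prod_i
   pi_{z_i}(beta) · p(beta)` with the Jacobian `c^{(K-1)p}`.  Plain data
   augmentation mixes the *scale* of the coefficients extremely slowly
   (each conjugate draw moves `|beta|` by O(1/√N)); without this move the
   probit layer cannot sharpen fast enough and clusters merge.
4. **Utilities** `Y | Z, beta`: exact redraw of the constrained Gaussian
   `N(X beta, I) | argmax = z` by vectorized rejection sampling, with a
   grid inverse-CDF fallback for rows with small acceptance probability.
   Steps 2+4 together are a valid *blocked* draw of `(Z, Y)`; a partial
   Gibbs pass over stale utilities after a collapsed label draw would not
   leave the joint invariant, which is why the redraw is exact.
5. **Coefficients** `beta | Y`: conjugate normal; reference row reset to 0.

All steps are invariant kernels for the joint posterior over
`(Z, P, beta)` (utilities are regenerated exactly before every use, so the
marginal-chain view is rigorous).  The per-sweep data log-likelihood
`Σ_i loglik_i(z_i)` is traced for every sweep and drives multi-run
retention.

**Optional relabeling move.** A Metropolis transposition of the reference
with another cluster (`beta'_k = beta_{tau(k)} - beta_j`; labels and
frequencies relabeled) leaves the probit label prior and the genotype
likelihood exactly invariant, so it accepts with just the coefficient
prior ratio.  It lets the chain traverse the label-permutation symmetry of
the posterior and is used when the object of interest is the full label
posterior (e.g. the enumeration check).  It is **off by default**: for
membership estimation, deliberate within-chain label switching would
scramble Q matrices, the usual label-switching trade-off in mixture MCMC.

**Numerical choices.** `pi_k(x)` inside the sampler is computed with a
fixed 13-node Gauss-Hermite rule and a piecewise-linear Phi table
(float32); absolute error ≤ ~1e-4, i.e. the chain targets the
quadrature-induced model, indistinguishable from the exact one at the
tested resolution (the enumeration oracle, which uses exact adaptive
quadrature, agrees to TVD < 0.01).  The public `membership_probs` uses
adaptive quadrature (sums to 1 within 1e-8) or Monte Carlo.  Truncated
normals use the inverse-CDF method with clipping; in impossible far tails
(beyond ~1e-300 mass) draws degrade gracefully onto the truncation bound.
Argmax ties break to the lowest index (a measure-zero event under the
continuous model).  When `numba` is importable the two Gauss-Hermite
kernels are JIT-compiled; the numpy implementations are the reference and
remain the fallback.

**Initialization.** Labels start from k-means++ (`scipy.cluster.vq.kmeans2`)
on the standardized covariate columns when the design has any (per-run
randomness diversifies the ensemble), otherwise uniform at random; pinned
individuals start at the reference.  A short warm-up (default 50
iterations) adapts `(Y, beta)` to the initial partition with labels held
fixed, so the probit layer encodes the start before the first label sweep.
With `beta = 0` a first label sweep has a uniform label prior and would
erase any starting partition; the warm-up is what makes initialization
meaningful.  Warm-up and initialization only choose the starting point of
the chain; post-burn-in samples target the posterior regardless.  On the
five-island benchmark, covariate-coherent starts raise the fraction of
runs reaching the dominant (correct) mode from ~1/8 to ~9/10; runs stuck
in merged-cluster modes have visibly lower likelihood and are dropped by
top-run retention.

**Pinning.** Individuals flagged as the reference population are never
allowed to leave the reference cluster (their labels are not resampled),
mirroring the outgroup convention of the real application.

## Multi-run protocol

Chains are replicated with seeds spawned from one master seed
(`SeedSequence`); runs are ranked by mean post-burn-in data log-likelihood
("highest likelihood" retention is based on this mean, which is robust to
single-sweep noise) and the top `n_keep` kept.  Cluster columns are
aligned to the best run by exact optimal assignment
(`scipy.optimize.linear_sum_assignment`) on the K×K column-similarity
matrix — a deterministic, exact replacement for heuristic Q-matrix
alignment tools; the reference column is held fixed only when pinning
makes it identifiable across runs.  Aligned Q matrices are averaged
entrywise.  Misclassification against ground truth assigns each individual
its modal cluster and minimizes mismatches over label permutations, again
by exact assignment, so the rate is invariant to arbitrary numbering on
either side.

## Prediction and variable selection

*Estimated* membership is the post-burn-in label frequency per individual.
*Predicted* membership resamples stored coefficient draws, simulates
utilities from covariates alone, and takes argmax frequencies; averaging
the deterministic `pi_k` over coefficient draws is retained as a
cross-check.  The Pearson criterion correlates the flattened predicted and
estimated matrices (Fisher-z confidence intervals).  The cross-validation
score splits the loci at random into two halves, fits `n_runs` chains per
half, keeps the `n_keep` best, and scores each retained chain's label
samples on the held-out loci by the Dirichlet-multinomial marginal —
held-out locus frequencies are not part of the training posterior, so they
are integrated against their Dirichlet prior given the allele counts
implied by the sampled labels (a plug-in variant using posterior-mean
frequencies is available behind the same interface for sensitivity
checks); fold roles are then exchanged and the `2·n_keep` scores averaged,
with a 1,000-resample nonparametric bootstrap standard deviation.  Desk
defaults are 20 runs / keep 5; the large-ensemble protocol (500/50) is a
configuration choice.

## Synthetic designs (what the generators emulate)

**Hidden-regression design** (`simulate_regression_data`): covariates
uniform on (-1, 1), factor levels in equal blocks; utilities follow the
probit model exactly over the same standardized design the fitting
pipeline builds, so stored utilities re-derive the labels.  Defaults: K=3,
300 individuals, latitude-only truth `beta = [(0,0,0), (1.8, 3, 0),
(0, 6, 0)]` over (intercept, lat, long) — boundaries near the latitude
tertiles, giving three roughly equal clusters with moderate overlap — and
biallelic frequencies (0.2, 0.5, 0.8) per cluster at every locus.

**Five-island design** (`simulate_island_data`): ancestral frequencies
Dirichlet(1,...,1) per locus (clipped at 0.05 and renormalized to avoid
near-fixed alleles), subpopulation rows from the Balding-Nichols F-model
`Dirichlet(p_anc (1-F)/F)` so the expected F_ST ≈ F; 5 subpopulations ×
100 individuals, 10 loci × 5 alleles (microsatellite-like) by default.
Subpopulation centers sit equally spaced on a circle of radius 1 and
individuals scatter with isotropic sd 0.25, which leaves adjacent
subpopulations slightly overlapping (spatial-only Bayes error ≈ 2%,
matching the few-percent misclassification regime this benchmark is known
for).  An optional spurious covariate is standard normal, independent of
the subpopulation.

**What passing these benchmarks does not show.** The generators draw
unlinked loci in Hardy-Weinberg proportions with no admixture, no
isolation-by-distance continuum, no genotyping error and no missingness
(missing data are exercised by the I/O tests, not the benchmarks); real
data violate all of these to some degree.  Benchmarks at desk scale use
reduced ensembles (e.g. 20 runs/keep 5; 3-5 replicates) — the problem
sizes used by the test suite and the acceptance script are stated in the
tests themselves and were chosen as the package's desk-scale defaults.

## Known limitations

- K is fixed by the user; no admixture (continuous ancestry) and no
  correlated-frequencies prior.
- The merged-cluster local mode of the posterior is genuinely sticky;
  inference relies on the multi-run/retention protocol rather than on a
  split-merge move.
- Nominal-coverage caveat: a posterior interquartile range is a 50%
  credible interval; under a well-specified model its frequentist coverage
  of the generating value is ~50%, not higher, and the package makes no
  claim otherwise.
- Degenerate inputs: constant covariates and single-level factors are
  rejected at design construction; collinear designs raise an error naming
  the offending columns; a genotype observed where a cluster's frequency
  is exactly zero scores -inf and is logged.
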