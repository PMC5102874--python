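# Methods

## Model

`gpamds` models a pair of GWAS p-value vectors over a common set of M SNPs
as a four-component mixture. Each SNP carries a latent state
Z ∈ {00, 10, 01, 11} with probabilities (π00, π10, π01, π11); conditional
on the state the two p-values are independent, Uniform(0,1) where the SNP
is null and Beta(α_k, 1) — density α_k p^(α_k−1) — where it is associated
with phenotype k. The constraint 0 < α_k < 1 makes the non-null density
monotone decreasing, i.e. small p-values over-represented.

Assumptions worth stating explicitly:

* p-values of null SNPs are Uniform(0,1). Residual confounding (population
  stratification, cryptic relatedness) violates this and biases everything
  downstream; it must be dealt with before the p-values reach this package.
* SNPs are exchangeable and treated as independent draws from the mixture.
  Linkage disequilibrium makes real SNPs locally correlated; the point
  estimates remain sensible under weak dependence but the χ²(1) reference
  for the pleiotropy test and the FDR guarantee are derived under
  independence.
* A single Beta(α,1) shape per phenotype summarizes all of its non-null
  SNPs; heterogeneous effect sizes are absorbed into one shape parameter.

## Estimation

Parameters are fitted by EM. The E-step computes state responsibilities
r_tl ∝ π_l f_l(P_t1, P_t2) (in log space, normalized by logsumexp); the
M-step is closed-form: π_l ← mean_t r_tl and, for each phenotype, the
weighted Beta(α,1) maximum-likelihood update

    α_k ← − Σ_t w_tk / Σ_t w_tk log P_tk,

with w_t1 = r_t10 + r_t11 and w_t2 = r_t01 + r_t11.

Numerical choices:

* p-values are clipped to [1e−12, 1 − 1e−12] before any log or density
  evaluation (the Beta density diverges at 0); raw inputs are kept
  unmodified, the clipping lives entirely inside the model.
* α is clipped into [1e−6, 1 − 1e−6] at every M-step; mixing proportions
  are means of normalized responsibilities and need no clipping.
* Default start: π = (0.70, 0.10, 0.10, 0.10), α1 = α2 = 0.5 — a mild
  signal prior. The likelihood optimum has proven insensitive to the
  start (a seeded multi-start option, `n_starts`, exists and in our
  checks never found a better optimum than the default start).
* Convergence: absolute log-likelihood change < 1e−8 or relative change
  < 1e−6, with max_iter = 2000. The observed-data log-likelihood is
  non-decreasing along iterations by construction (asserted in tests).
  Non-convergence produces a warning and a flagged result, never an
  exception.
* The EM optimum was cross-checked against direct Nelder–Mead
  maximization of the 6-parameter observed-data likelihood on a 2,000-SNP
  fixture; log-likelihood and parameters agree to ~1e−6.

**Constrained (independence) fit.** Under H0: π11 = π1✻·π✻1 the joint
mixture density factorizes exactly into the product of two marginal
two-group models (Uniform + Beta(α_k,1), non-null weight q_k). The
constrained MLE is therefore obtained by fitting each margin separately
with the same closed-form EM and composing π00 = (1−q1)(1−q2),
π10 = q1(1−q2), π01 = (1−q1)q2, π11 = q1q2. The constraint then holds to
machine precision by construction.

**Non-identifiability on signal-free data.** When a phenotype has no
signal at all, a Beta component with α → 1 is indistinguishable from the
Uniform, and the split between π00 and a pseudo-uniform non-null component
is not identified: EM stops somewhere on a likelihood ridge. Identifiable
functionals — the fitted density, the likelihood gain over the all-null
model, FDR-controlled selections — are unaffected, and those are what the
tests assert. Fitted proportions for a phenotype should only be
interpreted when its fitted α is clearly below 1.

## Pleiotropy test

The LRT statistic is −2 log λ = 2(llf_unconstrained − llf_constrained),
referred to the upper tail of χ²(1). No boundary correction is applied to
the reference distribution; under the independence null the simulated
type-I error at nominal 0.05 is ≈ 0.045 and the KS distance between the
statistic and χ²(1) is ≈ 0.03 (500 replicates, M = 2,000), so the plain
χ²(1) reference is adequate at these sizes. p-values are floored at
1e−300 so downstream log10 transforms stay finite.

If EM convergence slack leaves the unconstrained fit marginally *below*
the constrained one (a ~1e−3 effect possible on null data), the
unconstrained EM is restarted from the constrained solution; monotonicity
of EM then guarantees the nested ordering and a nonnegative statistic
without clipping bias.

## FDR control

The local FDR of a SNP for a target hypothesis is its posterior null
probability: post00+post01 (phenotype 1), post00+post10 (phenotype 2), or
1 − post11 (both phenotypes). Global FDR is controlled by the direct
posterior approach: sort local FDRs ascending and take the largest
observed threshold κ whose running mean — the estimated FDR of the
implied selection — stays within the bound τ. Ties at κ are selected
together; if a tie group would push the estimate over τ the threshold
steps back to the previous distinct value. The boundary comparison uses a
1e−12 absolute slack so that selections whose running mean equals τ
exactly are not flipped by floating-point summation order. An empty
selection reports realized FDR 0 with an `empty` flag.

Two caveats, both visible in the validation suite: the guarantee is on
the *expected* FDP, so single-study FDPs fluctuate around τ with binomial
noise (SD ≈ 0.03 when ~100 SNPs are selected — individual replicates
exceeding 0.15 at τ = 0.1 are expected and observed); and plugging in EM
estimates instead of true parameters adds a small anticonservative bias
(replicate-mean FDP ≈ 0.10–0.11 at τ = 0.1 on benchmark data, vs ≈ 0.10
when selecting with the true parameters).

## Distances and the map

Pairwise pleiotropy p-values p_ij give s_ij = log10 p_ij ≤ 0 and
d_ij = s_ij − 2·min_{k<l} s_kl ≥ 0; stronger pleiotropy means smaller
distance. The alternative count-based distance uses
n_ij = log10(count_ij + 1) and d′_ij = 2·max n_kl − n_ij; the +1 offset
(a deliberate deviation: the plain log10 is undefined at zero shared
SNPs) is finite everywhere and preserves ordering. Shared risk SNPs for
a pair are counted by fitting the pair, selecting on the both-phenotype
local FDR at τ = 0.1 (default), with the intersection of the two
single-phenotype selections available as `method="marginal"`; the
diagonal holds per-phenotype counts from the marginal two-group fit.

Embedding uses classical (Torgerson) MDS: B = −½ J (D∘D) J, eigendecompose,
scale the top-2 eigenvectors by √eigenvalue — the algorithm behind R's
`cmdscale` with default settings (verified against a frozen `cmdscale`
reference to 1e−10). Negative eigenvalues (non-Euclidean D) are excluded
from coordinates and summarized as `negative_eigenmass`; fewer than 2
positive eigenvalues zero-pads the missing axes and sets a `deficient`
flag. Each eigenvector's sign is fixed so its largest-magnitude entry is
positive, making outputs platform-reproducible. The normalized stress
Σ(d−d̂)²/Σd² is reported as a diagnostic of planarity only; no stress
minimization is performed beyond the spectral solution.

## Simulator

A study design specifies M SNPs, per-phenotype risk fractions and Beta
shapes, and pairwise sharing fractions. The default benchmark
(`five_phenotype_design`) is: M = 10,000; five phenotypes; 20% risk SNPs
each; 75% of risk shared within pairs (1,2) and (3,4) in disjoint index
ranges; phenotype 5 fully isolated; risk p-values Beta(0.4, 1), null
p-values Uniform. Risk sets are laid out as deterministic contiguous
blocks, so realized counts and overlaps match the design exactly;
randomness enters only through the p-value draws (the mixture is
exchangeable over SNP index, so layout is statistically irrelevant).

Designed-zero sharing under the block layout means *structurally
disjoint* risk sets — negative dependence (π11 = 0 < π1✻π✻1), which the
pleiotropy test rightly detects. For simulations of genuinely independent
genetic bases (the null of the test, used for calibration studies) the
`layout="random"` option places each phenotype's risk set independently
and uniformly at random, giving hypergeometric overlap around
risk²·M. `independent_pair_design` packages that configuration.

What the simulator does *not* emulate: linkage disequilibrium, genotype
sampling, effect-size distributions, sample overlap between studies, and
confounding-induced null miscalibration. Passing tests therefore certify
the statistical machinery under the model's own assumptions, not
robustness to the ways real summary statistics violate them.

## Problem sizes used in validation

The test suite validates at the benchmark size M = 10,000 for parameter
recovery (20 replicates), FDR control (20 replicates) and map geometry
(20 replicates of the full 5-phenotype pipeline), and at M = 2,000 with
500 replicates for null calibration of the LRT — sizes at which each EM
fit takes well under a second and the estimator noise floors are
documented above. Replicate averages are reported for parameter-recovery
quantities because the single-fit sampling SD of the shared-fraction
ratio π̂11/π̂1✻ at these conditions is ≈ 10 percentage points
(the ratio of two noisy small proportions); the average over 20
replicates measures the same estimand with SE ≈ 2.4 points.

## Known limitations

* Pairs only: no joint likelihood over ≥ 3 phenotypes; K-phenotype
  structure is assembled from all pairwise fits.
* No standard errors on mixture parameters; uncertainty statements rest
  on the LRT and on simulation.
* No multiple-testing correction across the K(K−1)/2 pairwise tests; the
  map consumes raw p-values by design.
* SNP matching is exact string identity of identifiers — no positional or
  allele harmonization.
* The annotation-augmented variant of this model family (covariate-driven
  priors on association states) is out of scope.
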