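# Methods

## The structural model

A gene's K SNPs (additive coding, columns centered and scaled to unit
variance) are collapsed into one latent component g = Xw; the environment
variable z (standardized likewise) enters as e = w_E z; the latent
interaction is r, the elementwise product g∘e standardized after the
product (centered, then scaled). The phenotype model is

    y = β₁ g + β₂ e + β₁₂ r + C β_c + ε,

with all latent components under the standardization convention
Σg² = Σe² = Σr² = N. With a single environment variable the convention
forces w_E = √(N / Σz²) > 0 — the environment component is simply the
standardized exposure, so the reported w_E (always 1 on the internal scale)
carries no free information. The phenotype is centered and scaled to unit
variance internally; coefficients are rescaled back to phenotype units on
report, so the ridge penalty has a scale-free meaning across datasets.

The latent interaction r is centered before scaling. With uncorrelated
genotypes and exposure this is a no-op up to sampling noise; in general it
keeps the model's column space aligned with the intercept-adjusted ordinary
regression, which is what makes the single-SNP, unpenalized special case
collapse exactly onto OLS of y on {1, x, z, x·z}.

## Estimation

Parameters (w, B) minimize the penalized least squares

    φ = SS(y − ŷ) + λ_S·SS(W) + λ_S·SS(B)

by alternating least squares. Estimation runs on the unconstrained
parametrization: the standardization constraints are treated as an
*identification and reporting* convention, restored after convergence by
rescaling (w, β₁, β₁₂) onto the constraint scale (which leaves ŷ
untouched). The reason is structural: on the unconstrained parametrization
both block updates are exact penalized least-squares solves —

* **B-step.** Given the latents, B solves the ridge regression of y on
  [g, e, r, C].
* **w-step.** Given (w_E, B), ŷ is *linear* in w with design columns
  β₁·x_k + β₁₂·center(x_k∘e), so w solves a K-dimensional ridge regression.

Exact block minimization makes the objective trace monotone non-increasing
and the fixed point a stationary point of φ, which a derivative-free
optimizer run on the same objective confirms to ~1e-13 relative in the test
suite. Enforcing the constraints *inside* the penalty during the iteration
would break both properties (the prescribed ridge w-step would no longer be
an exact block minimizer). At λ_S = 0 the working scale of (w, B) is not
identified (only their products are); the constraint-scale report is still
unique up to sign, fixed by the convention Σw_k > 0 (flipping β₁ and β₁₂
consistently).

Both W and B are penalized by the single λ_S by default; a W-only penalty
variant is available (`penalize_b=False`). The alternative changes little
in practice because SS(B) is O(1) against a fit term of O(N).

All cross-products needed by the two solves are precomputed once per
dataset (Gram matrices of X, the centered interaction columns, z and C), so
one ALS iteration costs O(K³ + K²) independent of N, and a phenotype
permutation costs only the O(NK) refresh of the y-dependent products. This
is what makes 199–5000 permutation refits per gene practical genome-wide.

Convergence: relative change in φ below 1e-6 (default), cap 1000
iterations; non-convergence returns the fit with `converged=False` and a
warning. Weight initialization is w_k = 1/√K (deterministic) by default;
seeded random initialization is available and reaches the same coefficients
to ~1e-5 on well-posed problems. Because the objective is biconvex, ALS can
occasionally settle in a non-global fixed point on small noisy instances
(observed in roughly 1 of 10 random N = 30, K = 3 draws); `n_init > 1`
reruns the algorithm from seeded random weight initializations and keeps
the best objective, which restores agreement with a global derivative-free
search. The default is a single start — inside permutation loops every
replicate uses the same procedure, so calibration is unaffected, and the
restart cost is better spent on permutations. A gene component that is identically zero
raises a degenerate-component error; zero-variance genotype columns are
dropped from the fit (their weight contribution is zero) with a log entry.

## Ridge parameter selection

λ_S is selected by 5-fold cross-validation over 15 evenly spaced values in
[0, 0.5]. Each candidate is fitted on the training folds (standardization
statistics from the training fold only) and scored by held-out squared
prediction error; ties break toward the larger penalty. Fits along the
candidate path are warm-started from the previous solution. Under pure
noise with K ≈ N/2 the selector prefers a positive penalty in ≈97% of
repetitions. λ_S is then held fixed across permutation replicates:
re-running CV inside each permutation would change the meaning of the test
statistic and multiply the cost ~75-fold.

## Permutation inference

The interaction test statistic is |β₁₂| on the constraint scale
(two-sided), compared against B permutation replicates with the add-one
estimator p = (1 + #{|β₁₂*| ≥ |β₁₂|}) / (1 + B); ties count as
exceedances, so p ∈ [1/(B+1), 1] and no zero p-values occur.

Two schemes generate the replicates:

* **`freedman-lane`** (default): the phenotype is regressed on the
  nuisance design (all SNP main effects, the environment main effect,
  covariates); the residuals are permuted and added back to the nuisance
  fit. Replicates therefore retain the main-effect structure while any
  interaction signal is destroyed.
* **`phenotype`**: the raw phenotype vector is permuted. This is exact
  when y is fully exchangeable under the null (no main effects at all).

The default matters. The gene weights w are re-estimated inside every
replicate fit, and they serve the main-effect component and the interaction
component simultaneously. When a real genetic main effect is present but
the raw phenotype is permuted, the replicates contain no structure at all,
so the adaptive weights are free to chase noise in *both* the g and r
directions; the null |β₁₂*| is then stochastically larger than the
observed-data sampling distribution of β̂₁₂ (whose weights are anchored by
the real main effect), and the test becomes severely conservative — in our
null study with a genetic main effect (β₁ = 1, one causal SNP of weight
0.5, N = 500) the mean raw-permutation p-value is ≈0.77 instead of 0.5.
Freedman–Lane replicates keep the anchor and restore nominal behavior
(measured rejection rate 0.05–0.06 at α = 0.05 under the same conditions).
The raw scheme remains available, and is the exact choice for exchangeable
nulls.

Known limitation: under a *completely* empty model (no main effects either)
the Freedman–Lane nuisance regression overfits noise by (K+2)/N, which
shifts the bulk of the p-value distribution downward (mean ≈0.39 at
N = 500, K = 5) while the rejection rate at conventional levels stays
within binomial bounds. With K not small against N, prefer the raw scheme
if the design is plausibly exchangeable, or increase N.

Across genes, Benjamini–Hochberg q-values (statsmodels) and the Bonferroni
threshold α / n_genes are reported.

## Competitor tests

Each SNP is tested by OLS of y on {1, x_k, z, x_k·z, covariates} with a
two-sided t-test on the product term (collinear designs return p = 1 with a
warning). The K p-values are combined by:

* **minP**: p = 1 − (1 − min p)^Me with the Li–Ji effective number of tests
  (eigenvalues of the genotype correlation matrix).
* **GATES**: min_j Me·p_(j)/Me_(j), effective numbers
  Me = K − Σ(λ_i − 1)₊ computed on the p-value correlation matrix obtained
  from genotype correlations by the sixth-order polynomial map (a switch
  allows |r| directly).
* **tTS / tProd**: truncated tail strength (1/K)Σ_{p_(j)≤τ}(1 − p_(j)(K+1)/j)
  and truncated product Π_{p_j≤τ} p_j with τ = 0.05 (configurable); no
  convenient analytic null exists under LD, so both use the same
  phenotype-permutation engine (the SNP-level designs are fixed, so the
  permuted t-tests are exact and the replicates vectorize over
  permutations). Under independence the truncated-product permutation
  p-value reproduces the closed-form null CDF within Monte-Carlo error.

Variance-component kernel interaction tests (GESAT/iSKAT-style) are out of
scope; externally computed p-value tables can be merged into the scan
output by the user.

## Synthetic data generator

Genotypes: per subject, two independent haplotypes are drawn from an AR(1)
standard multivariate normal (correlation ρ^|j−j′|), each thresholded at
Φ⁻¹(MAF_k) and summed. Marginals follow Hardy–Weinberg proportions exactly;
between-SNP correlation decays geometrically, a single-parameter surrogate
for haplotype-block LD. What it does *not* emulate: discrete block
boundaries, allele-frequency-dependent LD, rare variants (MAF is
restricted to [0.01, 0.5]), genotyping error and missingness. Passing
calibration and power tests on this generator therefore demonstrate
correctness of the inferential machinery under realistic *common-variant*
correlation, not robustness to every feature of array data.

Phenotypes follow y = β₀ + β₁·Σw_k x_k + β₂e + β₁₂·(Σw_k x_k)·e + ε with
ε ~ N(0, 1), e the standardized exposure (standard normal by default,
balanced Bernoulli available), and w_k = 0.5 on a random causal subset of
round(0.2·K) SNPs (minimum one).

Default study conditions: N = 500, K = 5, MAF ~ U[0.05, 0.4], ρ = 0.5,
β₀ = 0, β₁ = 1, β₂ = 0, β₁₂ = 0. The environment main effect is off by
default because the null study enumerates β₁ as the only nonzero structural
effect; users studying environment-confounded designs should set β₂ and
rely on the Freedman–Lane scheme, which absorbs it. Experiment harnesses
run 1000 datasets by default (the desk-scale checks in the test suite use
200 datasets and 199 permutations; the acceptance script states its sizes
explicitly) and report exact Clopper–Pearson binomial confidence intervals.
Per-dataset seeds derive from a master seed via `numpy` seed sequences, so
every table is bit-reproducible and all methods see identical datasets.

## Numerical and design choices

* Exact Hardy–Weinberg test (full enumeration of the conditional
  heterozygote distribution in log-space) rather than the chi-square
  approximation, so QC behaves at small minor-allele counts.
* Mean imputation of missing genotypes after QC filtering; imputed entries
  are non-integral and are excluded from subsequent hard-call counts, which
  makes QC idempotent.
* Genomic intervals are 1-based inclusive internally; BED input is
  converted on read. Gene flanks (default 20 kb) are inclusive at both
  boundaries and strand-agnostic.
* CV tie-break toward the larger penalty; permutation replicates that fail
  to converge are tallied and the result flagged above 5%.
* Per-gene random streams are derived from (master seed, CRC32 of the gene
  id), so scan output is identical regardless of gene order or worker
  count.

## Limitations

* Quantitative phenotypes only; no GLM link for binary/count outcomes.
* One environment variable per model; one gene per model (no pathway
  hierarchy).
* The permutation count bounds the smallest attainable p-value at
  1/(B+1); genome-wide significance at ~3×10⁻⁶ requires B well beyond the
  5000 default used for screening-level scans.
* λ_S fixed across permutations (see above); the CV-conditional coverage of
  the test is inherited from the selected penalty.
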