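# Methods

## The model

`banngp` implements genomic prediction with a two-layer, partially
connected Bayesian neural network whose architecture is dictated by
genome annotation. For a trait vector **y** (standardized de-regressed
proofs, sDRP) and a column-standardized dosage matrix **X** with J SNPs
grouped into G disjoint SNP-sets,

    y = sum_g h(X_g theta_g + 1 b1_g) w_g + 1 b2,

where `X_g` is the block of SNPs in set g, `theta_g` its input-layer
weights, `w_g` the hidden-layer weight of set g, and `h` the leaky ReLU
(`h(x) = x` for `x > 0`, else `0.01 x`). A SNP-set is either the SNPs
inside one gene, the unannotated SNPs sharing one intergenic interval, or
the SNPs inside one fixed 100-kb window.

Priors encode sparsity at both genomic scales:

* SNP weights: `theta_j ~ pi_t * sum_k eta_k N(0, sigma_k^2) + (1 - pi_t) delta_0`
  with K = 3 non-zero components (large / moderate / small effects);
* set weights: `w_g ~ pi_w N(0, sigma_w^2) + (1 - pi_w) delta_0`;
* inclusion probabilities: uniform priors on `log pi_t` over
  `[-log J, 0]` and on `log pi_w` over `[-log G, 0]`.

## Inference

Both layers are fitted by mean-field variational coordinate ascent with
closed-form per-weight updates, interleaved with EM updates of the
hyperparameters (component variances, mixture proportions, residual
variance), each of which maximizes the evidence lower bound (ELBO)
exactly. Training is two-stage: the SNP layer is fitted first; the hidden
neurons `H = [h(X_g beta_theta_g)]` are then deterministic functions of
the SNP-layer posterior means, and the set layer is a spike-and-slab
regression of y on the standardized columns of H. With centered X, y and
centered neurons the layer biases vanish on the standardized scale
(`b1 = 0`); the training mean of y plays the role of `b2` when
predictions are mapped back.

The uniform-on-log prior over the inclusion probability is handled with a
grid of L candidate values of `log pi` (default L = 20, equally spaced
over its support); each candidate is fitted to convergence with warm
starts along the grid, and posterior quantities are averaged with
normalized `exp(ELBO)` weights — under the uniform prior, the ELBO
approximates each candidate's log marginal likelihood. Iteration stops
when the ELBO improves by less than 1e-4 or after 10,000 iterations.
Variational parameters are initialized by random draws from the priors
(seeded); a deterministic zero-initialization mode exists for regression
tests. All variance hyperparameters are seeded from `sigma0_sq = 0.01`;
the K components start on a decade ladder (10, 1, 0.1) x `sigma0_sq` so
the mixture can specialize.

### Numerical choices

* **Component-variance floor.** Free EM updates of the slab variances can
  collapse a component onto the point mass (variance -> 0), after which
  that component is statistically indistinguishable from the spike and
  inclusion probabilities lose calibration. Component variances are
  therefore floored at `10 * tau0^2 / mean(x'x)` — roughly ten times the
  squared-error scale at which an effect becomes resolvable at sample
  size n. The floor is fixed at the initial residual variance so the EM
  constraint set is static and the ELBO stays monotone (checked to 1e-8
  slack in the tests).
* **Degenerate neurons.** A hidden column with zero variance after
  activation (possible when a set's fitted weights are exactly zero) is
  dropped from the set layer with a warning and carries zero weight.
* **Ties and ordering.** Coordinate updates sweep SNPs in column order;
  the grid is traversed from sparsest to densest candidate with warm
  starts.

### Outputs

Posterior inclusion probabilities are `PIP(j) = sum_k alpha_jk` at the
SNP level and `PIP(g) = gamma_g` at the set level. Phenotypic variance
explained is estimated at both scales,

    PVE_snp = V[X beta_theta] / (V[X beta_theta] + tau_theta^2)
    PVE_set = V[H beta_w] / (V[H beta_w] + tau_w^2),

with the sample variance as V. The SNP level captures additive signal
only; the set level routes non-additive (within-set interaction) signal
through the activation, which is why it is expected to exceed the SNP
level under epistasis.

## Comparators

* **GBLUP** — `y = 1 mu + Z g + e`, `g ~ N(0, G sigma_g^2)`,
  `e ~ N(0, D sigma_e^2)`; G is the VanRaden method-1 genomic
  relationship matrix and `d_ii = (1 - r_i^2)/r_i^2` from each animal's
  DRP reliability. After whitening by `D^{-1/2}` one eigendecomposition
  reduces REML to a bounded one-dimensional search over the variance
  ratio (profiled likelihood); this maximizer is validated against a
  brute-force likelihood grid and the BLUP solutions against a direct
  dense solve. Validation animals are predicted from the jointly built
  relationship matrix.
* **BayesB** — single-site Gibbs with fixed `pi = 0.95`, per-marker slab
  variances `~ scaled-inv-chi2(nu, S^2)` giving the scaled-t effect
  prior. `nu = 4.2` (field convention); `S^2` defaults to the value that
  matches an assumed prior genetic variance of 0.3 x var(y) spread over
  the expected non-zero markers; both are configurable.
* **BayesC-pi** — same sampler with one common normal slab variance and
  `pi` drawn each sweep from its Beta full conditional (uniform prior).
  Default chains are 50,000 iterations / 20,000 burn-in / thin 50; tests
  and the acceptance script use reduced chains (5,000 / 2,000 / 10),
  which the pi-recovery check shows are sufficient at the simulated
  sizes.
* **Random forest** — ensemble size and maximum depth tuned by an inner
  five-fold CV grid search on the training fold only (default grid
  M in {100, 300, 500}, depth in {5, 10, unlimited}).

## Synthetic data generator

No real cattle data ship with the package; the generator supplies
statistically faithful stand-ins for every stage.

* **Genotypes.** Dosages are sums of two haplotypes. Haplotype alleles
  come from a Gaussian copula: a latent AR(1) process (parameter
  `ld_rho`) thresholded at each SNP's allele frequency, so marginal
  frequencies are exact and adjacent SNPs are correlated within
  chromosomes. This is a controllable LD knob, not a coalescent
  simulation — it produces no long-range LD, no allele-frequency
  spectrum from drift, and no population structure. Default spacing is
  one SNP per 50 kb, the density of a bovine 50k chip.
* **Gene map.** Non-overlapping genes placed in equal slots per
  chromosome at a chosen density (default 10 genes/Mb, lengths 20–80 kb),
  leaving intergenic SNPs so both partitioning strategies are exercised.
* **Trait architecture.** Additive effects on standardized dosages drawn
  from the three-component mixture for a `pi_causal` fraction of SNPs
  (optionally confined to a chosen number of enriched SNP-sets); a
  fraction of sets holding two or more causal SNPs receive one pairwise
  product interaction with a large-component effect. Residual noise is
  orthogonalized against the genetic values and rescaled so the realized
  sample heritability equals the target exactly.
* **DRPs.** Per-animal reliabilities are uniform on a range (default
  0.5–0.9, bull-proof-like); the DRP is the true genetic value plus
  Gaussian noise with variance `var(tbv) (1 - REL)/REL`, matching the
  diagonal weighting of the mixed model, so the regression of true value
  on DRP has slope ~ REL and the squared DRP–truth correlation is ~ REL.

Default study conditions: h2 = 0.33 (within the 0.132–0.335 range of the
seven dairy traits the protocol targets), MAF uniform on [0.05, 0.5],
`ld_rho = 0.3`.

Because the generator mirrors the model's own prior family plus product
epistasis, passing recovery tests demonstrates the inference machinery is
correct and the directional claims hold under the stated conditions; it
does not demonstrate performance on real cattle data, whose LD structure,
relatedness and selection history the generator does not emulate.

## Evaluation protocol

Five-fold cross-validation repeated five times; every method consumes the
identical fold plan (enforced by a fold hash in the results) and the
identical standardized DRPs. DRP standardization constants come from the
training fold only. Per validation fold: accuracy
`cor(sDRP, PV)/r_bar` with `r_bar` the mean square-root DRP reliability
of the validation animals; dispersion as the OLS slope of sDRP on PV; and
MSE. Fold-level ratios are averaged to replicate level, then over
replicates. Methods are compared by paired two-sided t-tests on the five
replicate means (df = 4), Bonferroni-adjusted over method pairs within a
trait; pairing is the conservative choice given shared folds.

Genotype QC removes SNPs with MAF < 0.01 or a 1-df chi-square
Hardy–Weinberg test P < 1e-6 (an asymptotic stand-in for PLINK's exact
test, adequate at simulated sample sizes). Loaders reject missing
genotypes by default (linkage-based imputation is out of scope); an
explicit flag fills per-SNP mean dosages.

The DRP reliability bookkeeping (`lambda = (1 - h2)/h2`,
`ERC = lambda REL/(1 - REL)`, `r2_DRP = ERC/(ERC + lambda)`) is carried
verbatim even though it algebraically collapses to `r2_DRP = REL`; the
property suite asserts the identity.

## Problem sizes

The shipped tests and the acceptance script run the full protocol at
n = 800–2000 animals and J = 400–1000 SNPs with reduced MCMC chains and a
2x5 CV for the multi-seed directional checks; these sizes were chosen so
that recovery targets (heritability, pi, effect correlations) are
well-powered while the whole suite completes on a single CPU. Defaults in
the code (full 5x5 CV, 50k-iteration chains) reflect the full protocol.

## Known limitations

* The two layers are trained in sequence; the SNP layer is never refit
  conditional on the set layer. Joint training could propagate set-level
  sparsity back to SNP weights.
* The grid interpretation of the L candidate sparsity levels is one
  reading of multi-model averaging in this family; alternatives (e.g.,
  stochastic search) exist.
* The leaky-ReLU hidden layer captures within-set non-additivity only
  through a kinked transform of the set's additive score; purely
  antagonistic interactions with no marginal signal are invisible to it.
* The HWE filter is asymptotic, not exact, and the generator's LD model
  is first-order autoregressive only.
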