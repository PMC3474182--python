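# Methods

## Model and training procedure

The package fits single-hidden-layer feed-forward networks
t̂ᵢ = b + Σₖ wₖ·g(bₖ + **p**ᵢ'u[k]) to quantitative phenotypes, with a
hyperbolic-tangent (or identity) hidden activation and a linear output.
Two non-identifiabilities of the general formulation are resolved up front:
the outer regression coefficient *c* is fixed at 1 (with a linear output, *c*
and the wₖ only appear as products), and the outer bias *b* is removed by
centering the targets rather than estimated (it can be made trainable via
`Architecture(outer_bias_trainable=True)`; it is then excluded from the
weight penalty).

All remaining weights and neuron biases receive an isotropic Gaussian prior
N(0, σ²_w); residuals are N(0, σ²).  With α = 1/(2σ²_w), β = 1/(2σ²), the
MAP weights minimize F = β·E_D + α·E_W.  Training alternates:

1. one damped Gauss–Newton (Levenberg–Marquardt) step
   (2βJ'J + 2αI + λI)Δw = −∇F, accepted only if F does not increase
   (λ ×10 on rejection, ×0.1 on acceptance, caps 1e−12/1e10);
2. the effective number of parameters γ = m − 2α·tr H⁻¹ from the
   Gauss–Newton Hessian H = 2βJ'J + 2αI (Cholesky; symmetric-eigenvalue
   fallback with clipping at 1e−12 if the factorization fails);
3. the evidence updates α ← m/(2(w'w + tr H⁻¹)) and β ← (n − γ)/(2E_D).
   A config switch selects the classical alternative α ← γ/(2E_W); the two
   rules share the same fixed point.

Stopping requires both an optimized F at the current (α, β) (max-abs
gradient < 1e−7, or relative F change < 1e−8 over 5 consecutive accepted
steps) and converged hyperparameters (relative (α, β) change below
`hyper_rel_tol`, default 1e−9), subject to a 1000-epoch cap.  A final LM
polish at the converged (α, β) makes the reported weights the exact MAP for
the reported hyperparameters.  Training is deterministic given the seed.

**Initialization.** Weights start N(0, 0.1²); α starts essentially at zero
(1e−6) and β at 1, so the first LM steps fit the data nearly unregularized
before the evidence updates take over.  This matters for nonlinear
architectures: starting with an informative α (e.g. 0.01) and updating every
step shrinks the tanh units into their linear regime before LM can locate
curvature directions, and the loop then terminates at a strictly linear
solution.  The near-zero start is also the convention of the standard
Bayesian-regularization backpropagation implementations.

**Early stopping.** Validation-set early stopping (restore-best, patience 6)
is available but off by default: with the evidence updates active, the
validation MSE trajectory is non-monotone during the hyperparameter burn-in,
and the best-MSE epoch can be the near-zero initial model (whose MSE equals
the target variance), so the two mechanisms conflict.  The cross-validation
driver leaves stopping to the evidence loop unless a scheme with a
validation part and `early_stopping=True` is requested explicitly.

## Input representations

The infinitesimal additive model t = u + e, u ~ N(0, Aσ²ᵤ) can be read as a
one-neuron linear network in three ways, all provided by
`feature_matrix`: rows of the Cholesky factor C of A (or G), rows of the
relationship matrix itself, or rows of its inverse.  A is built from a
pedigree by the tabular method (founders non-inbred and unrelated; unknown
parents contribute zero; diagonal 1 + F).  G follows the centered-codes
recipe Z = M − E, G = ZZ'/(c·Σμ(1−μ)), with E the Hardy–Weinberg
expectations and c the ploidy (2 for 0/1/2 SNP codes; for dominant 0/1
markers the formula generalizes to E = μ and denominator Σμ(1−μ)).  Allele
frequencies default to in-sample estimates; training-set-only frequencies
can be supplied.  `centered_markers` mode exposes Z itself; with
`normalize=True` it is divided by √(c·Σμ(1−μ)) so PP' = G and the prior
weight variance maps onto additive variance per unit of average
self-relationship — this is the representation on which h² = β/(α+β) is a
calibrated heritability estimate (diag G ≈ 1).  Self-relationships are kept
in each individual's input row.

Inputs and targets are min-max scaled into [−1, 1] per variable, with
statistics estimated on the training partition only; predictions are
back-transformed, and MSE is reported on both scales.  A constant variable
maps to the range midpoint and is flagged.  The MAF filter removes markers
with minor-allele frequency strictly below the threshold (default 0.05);
missing genotypes are imputed by Binomial(ploidy, p̂ⱼ) draws from the
marginal genotype distribution.  Default order: filter → impute → scale.

## Genetic interpretation

Breeding values are input-weighted gradients,
BVᵢ = **p**ᵢ' Σₖ wₖ(1 − tanh²(bₖ + **p**ᵢ'u[k]))·u[k], evaluated at each
individual's observed inputs; for identity activations this is exactly the
linear marked breeding value **x**ᵢ'β.  Values are reported on the scaled
space and mapped to trait units through the slope of the target scale
record.  Input importance is each input's share of the summed absolute
input-to-hidden strengths (optionally weighted by |wₖ|); the alternative
readings of "all coefficients" are a config switch.

## Synthetic data generator

`simulate` produces biallelic SNP (0/1/2) or dominant (0/1) genotypes at
independent loci with allele frequencies Uniform(0.05, 0.95) — linkage
equilibrium, matching the assumption under which the G denominator holds —
plus a multi-generation random-mating pedigree and phenotypes
t = g_add + g_epi + e.  Additive values come from `n_qtl` (default 20)
randomly placed QTL with Normal(0, 1) effects.  Epistasis (default topology
`directional`) is the synergistic model: the epistatic deviation is
quadratic in the polygenic score, i.e. pairwise products of centered codes
with rank-one effect structure e_jk = a_j·a_k — a low-dimensional
interaction that a small tanh hidden layer can in principle represent.  An
unstructured `random_pairs` topology is also available; its effective
dimension grows with the number of pairs and no small network is expected
to learn it.  Components are rescaled so the realized additive:epistatic
ratio and var(g)/var(t) = h² match the configuration exactly on the sample;
true additive and total genetic values are returned (and written to a
separate truth file by the CLI) for recovery tests only.

What the generator does **not** emulate: linkage disequilibrium, allele
frequency spectra shaped by selection or drift, dominance, genotype ×
environment structure, or family stratification between training and test
sets.  Passing tests on these data therefore certify the estimation
machinery (shrinkage calibration, heritability recovery, derivative
correctness, honest cross-validation bookkeeping) — not that the network
architectures will show the same relative performance on real genomic data,
where LD concentrates signal in far fewer effective dimensions.

## The nonlinear-versus-linear comparison

The repeated-cross-validation driver retrains each architecture from
scratch on every random partition (min-max scaling refit on each training
part) and reports mean ± SE of the testing-set Pearson r, MSE, γ, and E_W.
On the simulated epistatic benchmark (599 individuals, 300 LE markers,
h² = 0.6, half the genetic variance epistatic, 480/119 splits) the margin
of the 2-neuron tanh network over the linear network is small and
partition-dependent.  The analysis behind this is instructive: under the
isotropic Gaussian prior, representing an interaction requires
pre-activations of order one, i.e. a weight-norm investment whose prior
cost at the evidence-tuned α (≈10²) generally exceeds the likelihood gain
when inputs are independent and ridge predictions are strongly compressed.
Interaction-capturing solutions exist and are stable fixed points of the
evidence iteration on some partitions (test r gains of +0.05 to +0.15),
but on others the iteration settles at an effectively linear solution, so
the 10-repeat paired comparison is not reliably significant.  With
LD-structured inputs (lower effective dimension) curvature is cheaper and
the nonlinear margin widens; LD simulation is deliberately out of the
generator's scope.  The comparison, including its paired one-sided test, is
computed and reported as-is by the acceptance script.

## Numerical choices and problem sizes

Cholesky factorizations of finite-sample G matrices tolerate eigenvalues
down to −1e−8 of the largest (clipped via a 1e−10-scale diagonal jitter so a
true triangular factor exists).  The A⁻¹ feature mode refuses matrices with
condition number above 1e12.  LM linear solves use `numpy.linalg.solve` on
H + λI; tr H⁻¹ and log|H| come from a Cholesky of H.  Cross-validation
benchmarks train with `max_epochs=200` and `hyper_rel_tol=1e-6`: the
hyperparameter trajectories plateau well before these limits on the
benchmark sizes, and the looser tolerance does not change test metrics at
the reported precision.  The acceptance runs use n = 200–599 and p = 50–300;
these sizes give the closed-form oracles (ridge, exact Gaussian marginal)
headroom to agree to 1e−6–1e−8 while each full run stays within minutes on
one CPU.

## Known limitations

- Single hidden layer, single output; no classification, no multiple
  traits.
- The Laplace evidence is exact only in the linear limit; for tanh networks
  it is a local approximation around one mode, and the (α, β) iteration can
  select different modes on different data partitions.
- The tabular A-matrix construction is O(n²) memory and not intended for
  national-scale pedigrees.
- Validation-based early stopping and evidence updates interact poorly (see
  above); they should not be enabled together without inspecting the
  training history.
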