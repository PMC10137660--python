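# Methods

## Model

`mfikit` works with exact joint distributions over a small set of discrete
variables. The central objects and the relations between them are:

**Möbius inversion.** For a finite poset *P* with Möbius function μ (defined
by μ(x,x)=1, μ(x,y) = −Σ_{x≤z<y} μ(x,z) for x<y, 0 otherwise), the inversion
f(y) = Σ_{x≤y} μ(x,y) g(x) and the order-ideal sum g(y) = Σ_{x≤y} f(x) are
mutually inverse. On the Boolean algebra of subsets μ(x,y) = (−1)^{|y|−|x|};
on a product of chains μ factorises componentwise. Both closed forms are
verified against the recursion in tests, and a matrix test checks that the
recursive μ is the inverse of the zeta matrix on random posets.

**Information as inversion.** Higher-order mutual information is the Möbius
inversion of marginal entropy on the subset lattice,
MI(τ) = Σ_{η⊆τ} (−1)^{|η|+1} H(η); the generalized pointwise mutual
information is the analogous inversion of marginal log-probabilities of one
realization. Reversing the lattice order gives the dual quantities: MI*(∅)
is the MI of the full set, and MI*(X) = MI(T) − MI(T∖X) is the differential
mutual information (the effect of marginalising X out).

**Interactions as inversion.** The model-free interaction (MFI) of a
variable set τ in background T is the iterated Boolean finite-difference of
log p evaluated with T∖τ at 0, equivalently the Möbius inversion of the
background surprisal S_{η;T} = log p(η=1, T∖η=0):

    I(τ;T) = Σ_{η⊆τ} (−1)^{|η|−|τ|} log p(η=1, T∖η=0).

Both routes are implemented independently (`mfi` differences log p;
`mfi_moebius` drives the lattice engine) and their equality is asserted on
random tables rather than assumed. MFIs are exactly the couplings of the
generalized Ising model: `mfi(boltzmann(J), S) == J_S` to 1e−10 is the
flagship oracle of the test suite. Dual interactions invert surprisal on
the order-reversed lattice; the dual of a singleton X equals the interaction
of the remaining variables with X fixed at 1, which is also tested via an
explicit conditional-table computation.

**Categorical interactions** replace the 0→1 step by an arbitrary increasing
transition x₀→x₁ per variable on the chain-product state lattice, with all
non-participating variables at 0. They are additive along chained
transitions and reduce to the binary MFI when every arity is 2.

## Sign and log conventions

* Interactions are in natural-log ("energy") units so they coincide with
  Ising couplings; entropy, MI and pmi default to base 2 (bits). Every
  information function takes a `base` argument; the CLI exposes `--base`.
* Background surprisal is +log p (not −log p); this is the orientation under
  which the derivative and inversion routes coincide.
* The pmi sign convention is fixed by requiring the two-variable reduction
  to equal log[p(x,y)/(p(x)p(y))].
* The inversion of MI back to entropy is H(τ) = Σ_{η⊆τ} (−1)^{|η|−1} MI(η)
  (alternating in the order of η); the round trip against directly computed
  entropy is tested on random tables.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| gate `p`, `eps` | derived / 1e−4 | legal and illegal state probability of a noisy logic gate, m·p+m·ε=1. ε=0 (the uniform truth table) is allowed: entropy-based results use it; interactions there are non-finite and flagged. |
| dyadic/triadic `eps` | 1e−4 | illegal-state probability; legal states get p=(1−56ε)/8; valid for 0 ≤ ε < 1/56. |
| `smoothing` (estimate_joint) | 0 | per-state pseudocount α; prob = (count+α)/(M+αK). No silent smoothing anywhere else. |
| `root_p`, `sigma2`, `n_samples` | 0.5, 0.1, 10⁴ | simulator: Bernoulli rate of orphan nodes, Gaussian noise variance, sample size. |
| `n_boot`, `alpha` | 500, 0.05 | bootstrap resamples and significance level in the association panel. |
| Boltzmann enumeration guard | 20 variables | exact 2ⁿ enumeration only; no MCMC. |

## Synthetic-data generator

`causal_sim.simulate` draws i.i.d. rows from a structural process on a
3-node DAG: orphans ~ Bernoulli(root_p); every other node (topological
order) is the product (multiplicative) or mean (additive) of its binarized
parents plus N(0, σ²), thresholded at 0.5 (which also clamps values outside
[0,1]). The threshold convention is a design choice; only "rounded to 0 or
1" is inherent to the process. For chains and forks the two dynamics
coincide, so the four preset DAGs give six scenarios.

What the generator does *not* emulate: real data with unobserved
confounders, non-binary noise, cyclic feedback, or limited sample sizes
where the all-zeros background state is rare. Passing tests show that the
metrics behave as the theory predicts under the stated process, not that
MFIs are robustly estimable in arbitrary empirical data.

Significance machinery (engineering choices): MFI and 3-point-MI
significance use a percentile bootstrap implemented as multinomial
resampling of the empirical state counts (exactly equivalent to row
resampling, much faster); pairwise plug-in MI is non-negative and
positively biased, so its label compares the estimate against the 95%
quantile of MI under an independence resample of the product of margins;
Pearson and partial correlations use their asymptotic tests
(partial correlation via `pingouin.partial_corr`, i.e. residual
correlation after regressing out the third variable).

## Numerical choices and degenerate inputs

* Zero-probability background states make surprisal −inf; interaction
  results then carry `finite=False` (values may be ±inf or NaN when
  infinities cancel) instead of raising, so whole-table scans complete.
* Joint tables validate non-negativity and unit mass to 1e−9; Möbius values
  are exact ints; interaction equalities are tested at 1e−10.
* Conditioning on a zero-probability assignment raises
  `DegenerateConditionError`; enumerating categorical interactions requires
  exactly three variables.
* Restricted backgrounds (T smaller than the full variable set) marginalize
  the omitted variables first. The induced bias vanishes when the omitted
  variables are independent of τ given the blanket — the only case tested;
  Markov blankets are parents ∪ children ∪ co-parents on a supplied DAG.

## Problem sizes

Exhaustive/exact checks run on ≤4 binary variables (tables of ≤16 states),
where every subset can be enumerated; the categorical examples use the
4×4×4 state space; simulation checks use 10⁴ samples per scenario with 500
bootstrap resamples. These sizes make the full suite run in seconds while
leaving every identity testable at 1e−10.

## Known limitations

* Binary/categorical variables only; continuous states do not form a
  lattice, so the definitions do not extend.
* Exact enumeration throughout; no estimation for large variable counts and
  no conditional-dependence-graph learning.
* The significance labels in the association panel are calibrated only in
  the sense of the bootstrap/asymptotic approximations used; sign patterns,
  not p-values, are the intended output.
* MFIs condition on observed variables and carry no causal or
  interventional interpretation by themselves.
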