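# Methods

## Model

At each site a population is in one of `|A| + C(|A|,2)(N−1)` states:
monomorphic `{a}` for an allele of the alphabet `A` (default A,C,G,T), or
polymorphic `{i a | (N−i) b}` for an unordered allele pair with `i` of `N`
virtual individuals carrying the first allele.  `N` is a discretization
parameter — the number of allele-frequency bins — not an effective
population size; the dynamics of a large real population are mapped onto a
small `N` by scaling mutation rates up accordingly.

The generator is `Q = Q_M + Q_D`.  Mutations act only from boundary
(monomorphic) states, `(Q_M){a}→{(N−1)a|1b} = q_ab`, with
`q_ab = μ ρ_ab π_b` from a reversible nucleotide model (JC, HKY with
`ρ = κ` on transitions, GTR, or custom symmetric exchangeabilities).
Frequency shifts follow the continuous-time Moran process,
`(Q_D){ia|(N−i)b}→{(i±1)a|(N∓1−i)b} = i(N−i)/N`, including the steps onto
the boundaries.  Disallowing mutation while polymorphic is an approximation
that is adequate while the heterozygosity stays below about 0.1; the
calibration routine warns beyond that.

For reversible mutation models the stationary distribution is available in
closed form (monomorphic mass ∝ `π_a`; polymorphic mass ∝
`μ ρ_ab π_a π_b N/(i(N−i))`); the generic assembly path solves for the null
left-eigenvector instead, and the two routes are cross-checked in the
tests to 1e−8 over random models.

Sites are independent (a composite likelihood with free recombination), so
the data enter only through site-pattern counts.

## Branch-length units

`Q` is normalized so one unit of branch length carries one expected event
(mutation or drift step) per site at stationarity; the applied constant is
exposed on the `RateMatrixSet`.  Because the stationary drift flux is
exactly `N−1` times the mutation flux and a single new mutant fixes with
probability `1/N`, the conversion from branch lengths in expected
substitutions per site to event units is exactly `N²`
(`events_per_substitution`).  The simulator and the inference engine share
the event convention, so recovery experiments are self-consistent;
experiment heights quoted in substitutions per site below are converted
with the `N²` factor.

## Heterozygosity calibration

θ is operationalized as the stationary probability that a site is
polymorphic.  This quantity is `μS/(1+μS)` for a model-dependent constant
`S`, hence strictly increasing in μ and exactly invertible;
`calibrate_heterozygosity` performs a bracketed Brent solve on the
numerically computed polymorphic mass so the same code path also serves
non-closed-form models.  A Watterson-type estimator computed from sampled
alleles would differ by sampling corrections; the stationary definition was
chosen because it is exact, monotone and shared between simulator and
inference.

## Γ mutation-rate heterogeneity

A global rate rescaling would wrongly accelerate drift together with
mutation, so heterogeneity is a mixture over `K` equal-probability
categories scaling only the mutation part: `Q_k = r_k Q_M + Q_D`, with site
likelihood `(1/K) Σ_k Pr(D|Q_k, T)`.  The `r_k` are the means (not medians)
of the K slices of a mean-one Gamma(α), computed from regularized
incomplete-gamma integrals and renormalized so their mean is exactly one.
Numerical bounds: α below 0.01 is rejected; α at or above 10⁶ is treated as
homogeneous.  All categories share one normalization constant derived from
the probability-weighted mean generator (which equals the homogeneous
`Q_M + Q_D` because the rates average to one); per-category normalization
would distort the meaning of the `r_k`.  Each category needs its own
spectral decomposition; the engine caches all K and reuses them across
branch-length proposals.

## Leaf likelihoods

An observation of `M` sampled alleles is mapped to a likelihood vector over
states by one of three strategies: `sampled` (binomially draw `N` alleles
from the observed frequencies, hard-assign the resulting state; seeded),
weighted binomial (state `{ia|(N−i)b}` scores the binomial probability of
the observed sample at success probability `i/N`; the default), and
weighted hypergeometric (sampling without replacement from the `N` bins;
requires `M ≤ N`, exact when `M = N`).  Monomorphic states are treated as
the `i ∈ {0, N}` limits within every compatible allele-pair column, with
the matching monomorphic state counted once.  Missing observations (`0,0,0,0`
cells) initialize all states to one.  Observations with three or more
segregating alleles cannot be represented and raise an error at
initialization (the file parser deliberately accepts them so that real
data can be loaded and cleaned).

## Inference

Pruning runs over compressed site patterns with per-node rescaling and
accumulated log factors; the root is closed with each category's stationary
distribution, which makes the likelihood invariant to root placement for
reversible models (asserted in the tests, not assumed).  Transition
matrices come from a symmetrized eigendecomposition
(`D Q D^{-1}` with `D = diag(√stationary)`); when a category's stationary
distribution has entries below 1e−8 — tiny rate categories under small α —
the rounding error of that route grows like `ε·√(max/min)`, so the engine
falls back to Padé scaling-and-squaring for those categories.  Tiny
negative probabilities are clamped at 1e−12.

Optimization is coordinate-wise: each branch length gets a bounded 1-D
search on log scale (bounds 1e−8..10) using outer partial likelihoods so a
single branch update costs one transition matrix and one contraction; then
κ (0.2..100) or the five free GTR exchangeabilities (0.01..100), θ
(1e−6..0.25) and α (0.01..10⁶) are each refined by bounded Brent on log
scale.  After the first sweep the scalar brackets shrink to a local window
around the current value.  Sweeps stop when a full pass gains less than
`tol_lnl` (default 1e−4 log-likelihood units) or after 100 sweeps.  Base
frequencies default to the pooled empirical allele frequencies; a
maximum-likelihood mode (Nelder–Mead over softmax coordinates) is
available.  Whenever κ, the exchangeabilities or π move, μ is recalibrated
so θ retains its meaning as the optimized polymorphism parameter.

Topology search is exhaustive enumeration of unrooted topologies up to 8
taxa and NNI hill-climbing beyond (trees are kept in trifurcating-root
form, where every internal edge has exactly two interchange neighbours).
The nonparametric bootstrap resamples sites with replacement and, by
default, re-searches each replicate; support is the percentage of
replicates containing each input split.  Model ranking fits each candidate
and sorts by AIC = 2k − 2lnL or BIC = k·ln(n_sites) − 2lnL with a stable
sort; k counts free branch lengths plus free model parameters.

## Simulator

Per site: draw a category uniformly, draw the root state from that
category's stationary distribution, evolve along each branch by sampling
from the exact endpoint distribution `exp(Q_k t)` (no event-by-event
simulation needed; a Gillespie mode exists and is checked against the exact
route on small cases), then sample `M` alleles per leaf from the leaf
state's allele frequency — binomially by default, or hypergeometrically
(without replacement, `M ≤ N`), which reproduces the state exactly when
`M = N`.  Fixed seeds give bit-identical output.

Yule trees grow from a root split at rate λ per lineage, truncated at
height `h` (all tips contemporaneous), with `λ = (Σ_{i≤n} 1/i − 1)/h`.
That calibration makes `h` the expected root age of an `n`-tip tree; the
leaf count of the truncated process itself is a sum of two geometric
variables with mean `2e^{λh}` (≈1.37·n), not `n` — the tests assert the
process's own mean, and recovery experiments condition on exactly `n` tips
by rejection.

## Study conditions for the recovery experiments

The Γ-shape experiments in `tests/test_acceptance.py` use 12-taxon Yule
trees of height 0.01 expected substitutions per site (= 1.0 event units at
N=10), HKY κ = 6.25, π = (0.3, 0.2, 0.2, 0.3), θ = 0.0025, K = 4,
α ∈ {0.3, 1.0, 5.0}, M = 10 samples per population, weighted-binomial
leaves, and fits on the true topology from a cold start (all branch
lengths 0.3, κ = 2, θ from the observed polymorphic fraction, α = 1).
Problem sizes are 2×10⁵ sites and three replicates per α — a deliberate
scale-down of the original 10⁶-site, ten-replicate design.  At this size
the Fisher information bounds what any estimator can achieve: profile
curvature puts the per-replicate standard error at roughly 4% for κ and
8–40% for α (worst at α = 5, where the likelihood is nearly flat towards
homogeneity), so the recovery tests document those floors rather than the
published full-scale error bands; see the test docstrings.  The
branch-length metric is the original Kuhner–Felsenstein branch score (sum
of squared differences over the union of splits) between height-normalized
true and estimated trees, relative to the squared norm of the true branch
lengths.

The high-heterozygosity robustness check uses θ ∈ {0.01, 0.1} on trees of
height three coalescent units, mapped to event units as
`1.5·θ·N²` (three `N_e`-generation epochs at substitution rate θ/2 per
unit), 2×10⁴ sites, homogeneous rates.

## What the synthetic data does not emulate

The generator-and-simulator pair is exactly matched, so recovery tests
validate the estimation machinery, not robustness to model violation.  Real
data differ in ways the simulator does not produce: linkage between sites
(the composite likelihood treats sites as free-recombining), selection,
more than two alleles segregating at a site, sequencing error, uneven and
site-dependent sample sizes, and mutation processes that are nonreversible
or vary along the tree.  Population structure within a sampled population
and gene flow between populations are likewise outside the model.

## Known limitations

* Observations with more than two segregating alleles are rejected rather
  than collapsed.
* The weighted-binomial strategy initializes polymorphic states to nonzero
  values for monomorphic observations and therefore slightly inflates
  fitted heterozygosity; weighted hypergeometric reduces this but is
  undefined for `M > N`.
* Exhaustive topology search is limited to 8 taxa; NNI hill-climbing makes
  no global optimality claim.
* The invariant-sites model is intentionally absent: with a zero mutation
  rate polymorphic states have zero stationary mass, so observed
  polymorphic sites could not be assigned to any state; small-α Gamma
  categories cover nearly-invariant sites instead.
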