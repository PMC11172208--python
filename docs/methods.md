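# Methods

This note records the model implemented by `fraccs`, the numerical
choices behind it, and the limitations of the synthetic validation.

## Optimizer

Cuckoo search maintains `n_nests` persistent positions inside a box.
One generation consists of:

1. **Global proposals.** `n_cuckoos_per_iter` candidates are drawn by
   the Lévy-flight walk `x' = x_j + β·L` from a random donor `x_j` and
   clipped to the box. Each candidate is compared against one random
   nest and replaces it only if *strictly* better, so ties never churn
   the population.
2. **Abandonment.** The ⌈Pa·n_nests⌉ worst nests — never the incumbent
   best — are rebuilt unconditionally by the local walk
   `x' = x_j + β_s ⊙ H(Pa − v) ⊙ (x_p − x_q)`, with fresh per-coordinate
   uniforms `v`, `β_s`, and two distinct random peers `p, q ≠ j`.
   Keeping the best nest out of abandonment gives elitism: the recorded
   best fitness is monotone non-increasing, which the tests assert for
   arbitrary seeds.

Lévy steps use the Mantegna construction, `u/|v|^(1/λ)` with
`σ_u(λ)` from the closed-form gamma expression. Although the target
power law is nominally defined for tail exponents in (1, 3), the
Mantegna scale constant contains `sin(πλ/2)`, which vanishes at `λ = 2`
and turns negative beyond; the implementation therefore restricts
`λ` to (1, 2). The default `λ = 1.5` sits comfortably inside.

## Fractional gradient

The Caputo derivative of order `α ∈ (0, 1]` from reference `c` is
approximated coordinate-wise by the truncated series

    D^α f(x) ≈ Σ_{v=1}^{M} f^(v)(x) / Γ(v+1−α) · (x − c)^(v−α),  M ≤ 4.

Numerical choices:

- **Derivatives** `f^(v)` come from central finite-difference stencils
  of orders 1–4 that share evaluation points, so one table costs at
  most `1 + 4·d` objective evaluations. The step is
  `fd_step × mean box width` (relative, so rescaling the box rescales
  the stencil). Central stencils are second-order accurate; they are
  exact on quadratics but carry `O(h²)` truncation error on higher
  polynomials, which the oracle tests tolerate explicitly.
- **Signed powers.** `(x − c)^(v−α)` is evaluated as
  `sign(d)·|d|^(v−α)` for non-integer exponents so the series stays
  real for `x < c`, but as the plain real power when the exponent is an
  integer. This makes the `α = 1, M = 1` case reduce *exactly* to the
  ordinary finite-difference gradient on either side of the reference,
  which would fail under the signed convention (`sign(d)·|d|⁰ = −1` for
  `d < 0`).
- **Non-finite values** from a pathological objective propagate as NaN
  out of the gradient routine; the optimizer sanitizes them to zero
  before using the gradient as a step modulator, so one bad stencil
  cannot launch a nest to infinity.

## Fractional cuckoo search

CFO-CS replaces both walks' step with a coordinate-wise product of the
original random step and the fractional gradient:

- the **global** walk evaluates the gradient at the donor nest with a
  reference averaged over three randomized pulls
  `x_j − r_m (x_best − x_j)`, `r_m ~ U(0,1)`;
- the **local** walk uses the current worst nest as the reference.

The derivative table is computed once per generation at a snapshot of
the incumbent best and reused for every proposal; series assembly per
proposal is pure arithmetic. Gradient overhead is therefore bounded by
`2·M·d` objective evaluations per generation.

**Degenerate-modulation fallback.** When the gradient factor is
identically zero — which happens systematically whenever the donor
nest *is* the best nest, because the exploration reference collapses
onto it — the multiplicative update would produce an exact copy of the
donor. Greedy replacement then clones the best nest until the
population collapses to a single point and the search freezes (observed
empirically: median final sphere fitness 15.0 versus 0.5 for plain CS).
The implementation falls back to the corresponding plain CS walk for
exactly those all-zero-gradient proposals. With the fallback, CFO-CS
beats plain CS on 9 of 10 paired sphere seeds (median 0.12 vs 0.50).

## Feature selection

Wrapper selection runs the optimizer over `[0, 1]^d`, binarizing at a
strict `> 0.5` threshold. Fitness is
`w·η + (1−w)·|F|/d` with `w = 0.99`: classification error dominates,
subset size breaks ties. `η` is the error of a k-NN classifier
(`k = 7`, Euclidean) on a stratified 70/30 validation split of the
training partition; an outer stratified 70/30 split reserves a test
partition that the search never sees. The empty mask gets an infinite
fitness sentinel. Mask evaluations are memoized by mask key — the
search revisits masks constantly, and the cache is a pure memoization
with no effect on results.

Default optimizer parameters (15 nests, 10 proposals, Pa = 0.25,
β = 0.3, λ = 1.5, 100 generations, α = 0.7, M = 4) follow the reference
parameterization this implementation targets; they are ordinary cuckoo
search settings and none were tuned against the test suite.

## Metrics

Accuracy, precision, specificity, sensitivity, F1 and the Matthews
correlation coefficient are computed from the four confusion-matrix
cells. Zero denominators yield NaN rather than an arbitrary 0 — except
that MCC is genuinely −1 (not undefined) when every prediction is wrong
but all four margins are positive. Percent reports round to two
decimals in the fixed column order Acc, Pre, F1 Score, Spe, Sen, Mcc.

## Synthetic validation and its limits

The generators exist so the pipeline can be validated offline:

- `generate_features` plants `n_informative` columns whose class means
  differ by `effect_size`, optional correlated redundant copies, and
  pure-noise fillers, with a seeded shuffled column order. It is a
  deliberately simple Gaussian class-shift model — no heavy tails, no
  label noise, no nonlinear interactions — so recovery results
  demonstrate mechanism, not clinical performance.
- `generate_toy_images` builds two texture classes (stripe frequency,
  orientation and speckle density differ) that HOG+LBP separate almost
  perfectly; real fundus photographs are far harder.
- `MockEmbeddingProvider` is a seeded random projection standing in for
  pretrained-network embeddings; it preserves dimension bookkeeping and
  determinism but carries no semantics. Real embedding backends can be
  plugged in through the same `EmbeddingProvider` protocol.

Problem sizes used in the acceptance script (10-D sphere, 200×20
planted matrices, 10 seeds) are this package's own choice: large enough
that the convergence-ordering and recovery properties are stable across
seeds, small enough to run in seconds.

## Limitations

- The convergence advantage of CFO-CS is demonstrated on smooth
  synthetic objectives; on the discrete mask landscape the gradient is
  a heuristic signal, not a true descent direction.
- k-NN fitness uses a single validation split per problem seed, not
  cross-validation; variance across splits is absorbed by the
  multi-seed medians rather than modeled.
- HOG and LBP block lengths are adapted (truncated/zero-padded) to the
  declared 80/66 dimensions for bookkeeping compatibility; the natural
  lengths are 81 and 59.
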