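# Methods

## Model

A well-mixed population of `Z` individuals repeatedly plays the N-person
prisoner's dilemma (a public goods game) in randomly sampled groups of
size `N`. Each round, a cooperator contributes `c`; the pot is multiplied
by the enhancement factor `F` and split equally, so with `k` contributors
a defector earns `F·c·k/N` and a cooperator `F·c·k/N − c`. After every
round another follows with probability `w`, giving a geometric number of
rounds with mean `m = 1/(1−w)`.

Players use *reactive strategies*: an `(N+2)`-bit rule
`b^−1 b^0 … b^N` where `b^−1` fixes the opening move and `b^q` the move
after observing `q` cooperators in the previous round (1 = cooperate).
The full space has `2^(N+2)` strategies. Intended acts are inverted with
the execution-error probability `ε ∈ [0, 0.5]`; the error applies to the
opening move as well (an act is an act; nothing distinguishes round one
mechanically). The *all-or-none* rule — cooperate only after unanimous
cooperation or unanimous defection (`b^0 = b^N = 1`, interior bits 0) —
reduces to Win-Stay-Lose-Shift at `N = 2`.

Selection follows the pairwise-comparison rule: a focal individual
imitates a random other member with the Fermi probability
`[1 + exp(−β Δf)]⁻¹`, where `β ≥ 0` is the intensity of selection and
`Δf` the fitness advantage of the model.

## Exact game engine

Within a group whose members come from two behavior profiles, all players
sharing a profile are exchangeable and payoffs are linear in the
contributor count, so the per-round dynamics reduce exactly to a Markov
chain on the total cooperator count `q ∈ {0..N}`. Rows are sums of two
independent binomials (one per profile); the opening distribution comes
from the `b^−1` entries. The discounted round occupancy has the closed
form `u = (1−w)·v0(I − wM)⁻¹`, and per-round expected payoffs follow from
`u` and each profile's cooperation probabilities. This "average payoff
over all rounds" convention equals `E[total payoff]/E[rounds]`; the Monte
Carlo cross-checks therefore use the ratio-of-means estimator, whose
delta-method standard error makes the 3-SE agreement tests well-posed
(the naive mean of per-playout averages estimates a different quantity).

Fitness in a population with `k` players of strategy A is the
hypergeometric average of group payoffs over the `N−1` co-players drawn
without replacement from the remaining `Z−1` individuals. Fixation
probabilities of single mutants use the standard birth-death ratio
formula with `T⁻/T⁺ = exp(−β Δf)`, evaluated with cumulative log-sums
(logsumexp), which is exact and overflow-proof at strong selection.

## Small-mutation limit

For mutation rates `μ ≪ 1/Z` the population is monomorphic almost
always; evolution reduces to an embedded Markov chain over strategies
with off-diagonal transitions `ρ(j invades i)/(|S|−1)`. Its stationary
distribution `τ` is solved as a linear system with the normalization
constraint (least squares, fixed-point residual checked against 1e-10),
never by power iteration. Derived statistics: the stationary bit
distribution `B^q = Σ_i τ_i b_i^q`, dominance calls at the configurable
thresholds 0.75/0.25, and the cooperation level `η = Σ_i τ_i C_i/N`
with `C_i/N` the discounted monomorphic cooperation rate.

The full-space pipeline needs every ordered pairwise fixation
probability. Because a pure strategy's per-act cooperation probability is
either `ε` or `1−ε`, a fixed group composition admits only four distinct
transition rows (one per ordered bit pair); every pair's chain is
assembled by indexing those rows and all `C(|S|,2)` chains are solved in
one batched linear solve (chunked at 200k pairs to cap memory). The
generic per-pair route through the game engine remains the reference
implementation — mixed-profile subsets (e.g. the random strategist) use
it — and the test suite asserts the two routes agree to 1e-10. The full
`N = 5` pipeline (128 strategies, 8128 pair chains, 16256 fixation
probabilities) runs in about a second; a 31-point error sweep in a few
seconds.

Subset runs are supported because full-space runs at `N ≥ 8` grow as
`4^N`; `τ` is then set-relative and outputs are labeled accordingly. For
profiles without bits (RS), `B^q` uses the cooperation probability (0.5),
the natural generalization of a bit average.

## Agent-based validation

The simulator implements the finite-`μ` process event by event: focal
chosen uniformly; mutation to a uniformly random strategy from the set
with probability `μ` (the conventional uniform kernel), otherwise Fermi
imitation of a random other member. A "generation" for reporting is `Z`
events. By default fitness is the exact expected payoff given the current
composition: with at most two strategies present (the dominant case when
`μZ ≪ 1` and the run starts monomorphic) it is read from the precomputed
all-pairs fitness tables; with three or more coexisting strategies an
exact multivariate-hypergeometric enumeration over group compositions is
computed and cached. A sampled-playouts mode estimates fitness from
stochastic game playouts instead. Time averages are accumulated
event-weighted (exact, not thinned) with composition-change flushes;
standard errors come from ten block means.

### Problem sizes for the validation runs

Agreement between ABM time averages and the SML stationary distribution
is limited by the embedded chain's mixing: nearly neutral transitions
(e.g. flips of the opening bit) occur at rate `~μ/Z` per event, so the
autocorrelation time at `μ = 10⁻³`, `Z = 100` far exceeds any desk-scale
run over the 128-strategy space at `N = 5` (measured: per-bit deviations
of ~0.16 with block SEs of ~0.1 after 1e8 events — pure sampling noise).
The validation test therefore runs the full 16-strategy space at `N = 2`
with `Z = 30` and 1e8 events, where the chain mixes well: measured
per-bit agreement 0.01–0.03 with SEs ~0.02, comfortably within the 0.05
band, in about two minutes. This choice scales the *population*, not the
physics: μ, β, F/N, w and ε keep their headline values.

What the ABM does and does not show: it validates the population-genetic
reduction (embedded chain, fixation probabilities, stationary weights)
under the same exact game payoffs the analytics use. In analytic-fitness
mode it does not exercise game-sampling noise; the sampled-playouts mode
exists for that, at far higher variance.

## Defaults and parameter choices

| parameter | default | why |
|---|---|---|
| `c` | 1 | payoffs are linear in `c`; only `F/N` is reported |
| `F/N` | 0.85 (headline runs) | one-shot dilemma regime (`F < N`) |
| `w` | 0.96 | mean `m = 25` rounds |
| `ε` | 0.05 | small but non-negligible execution noise |
| `Z`, `β` | 100, 1.0 | headline finite-population conditions |
| AoN opening bit | 0 | results are insensitive to it; the two-strategy gradient analyses use `b^−1 = 0` |
| dominance thresholds | 0.75 / 0.25 | "same value more than 75% of the time" |

Bit order in integer ids (`b^−1` most significant) is a file-format
decision so ids are stable across runs; strategies also render as
`"b^−1|b^0…b^N"` strings (AoN at `N = 5` is `0|100001`).

## Numerical notes and limitations

- `(I − wM)` is nonsingular for all `w < 1` (spectral radius of `wM`
  below 1); no regularization is needed, including at `ε = 0` where the
  chain is deterministic.
- Gradient-of-selection roots are reported as the integer bracket of each
  strict sign change plus a linear interpolate; a root exactly on a grid
  point is not double-counted.
- At `β = 0` or `ε = 0.5` the embedded chain is exactly uniform; these
  limits are asserted in tests to 1e-8 or better.
- The interior-bit dominance at `N = 5` is borderline: this implementation
  gives `B^2 ≈ 0.266`, just above the 0.25 dominance threshold, while
  `B^1, B^3, B^4` are clearly defective-dominant and both edge bits exceed
  0.98. The value is robust to the identifiable modeling conventions
  (opening-round error handling, with/without-replacement group sampling).
- Full-space analysis at `N = 10` (4096 strategies, ~8.4M pairs) is
  supported by the chunked pipeline but takes hours; sweeps at that size
  should use subsets.
- Strategies here react only to the previous round's total contribution
  count; longer memories, identity-conditioned strategies and structured
  populations are out of scope.
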