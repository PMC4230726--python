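# reactivepgg

Evolutionary dynamics of **reactive strategies in repeated public goods
games**: an exact small-mutation-limit analysis of the complete
`2^(N+2)`-strategy reactive space under finite-population Fermi dynamics,
plus a finite-mutation agent-based validator.

## The problem

Groups of `N` players repeatedly face an N-person prisoner's dilemma:
each round, cooperators contribute `c`, the pot is multiplied by `F < N`
and shared equally (defectors earn `F·c·k/N`, cooperators `F·c·k/N − c`
with `k` contributors), and another round follows with probability `w`
(mean rounds `m = 1/(1−w)`). A *reactive strategy* is an `(N+2)`-bit rule
`b^−1 b^0 … b^N`: the opening move plus one response per possible count
of cooperators observed in the previous round. Execution errors flip
intended acts with probability `ε`.

Evolution runs in a finite population of `Z` individuals under the
pairwise-comparison rule (imitation probability `[1+e^{−βΔf}]⁻¹`). In the
rare-mutation limit the population hops between monomorphic states and
the dynamics reduce to a Markov chain over strategies whose transitions
are single-mutant fixation probabilities; its stationary distribution
`τ_i` weights each strategy by the fraction of time the population spends
on it. From `τ` the package computes the **stationary bit distribution**
`B^q = Σ_i τ_i b_i^q`, dominant-bit calls (≥ 0.75 cooperative / ≤ 0.25
defective), and the **level of cooperation** `η = Σ_i τ_i C_i/N`.

The headline phenomenon: evolution selects the **All-Or-None** rule —
cooperate only after unanimous cooperation *or* unanimous defection
(`b^0 = b^N = 1`, interior bits 0) — which recovers from errors in one
round and reduces to Win-Stay-Lose-Shift at `N = 2`. Against
unconditional defectors it creates a coordination game whose barrier
shrinks as `F` grows, and it resists drift by unconditional cooperators.

All group payoffs are exact (Markov chain on the cooperator count,
discounted occupancy in closed form), all fixation probabilities are
exact (log-space birth-death products), and the full-space pipeline is
batched so the 128-strategy system at `N = 5` solves in about a second.
See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
from reactivepgg import GameParams, PopulationParams, run_sml

gp = GameParams.from_f_over_n(5, 0.85, w=0.96, eps=0.05)   # F = 4.25
res = run_sml(gp, PopulationParams(Z=100, beta=1.0))        # all 128 strategies

print(res.to_bit_frame().to_string(index=False))
print("eta =", round(res.eta, 3))
print(res.top_strategies(3).to_string(index=False))
```

Output:

```
 q        B        call
-1 0.334994   undecided
 0 0.988838 cooperative
 1 0.086189   defective
 2 0.265457   undecided
 3 0.138225   defective
 4 0.040236   defective
 5 0.994686 cooperative
eta = 0.739
 id strategy      tau  coop_rate
 33 0|100001 0.349678   0.718547
 97 1|100001 0.181514   0.754547
 41 0|101001 0.147840   0.723929
```

Both "edge" bits are cooperative-dominant (the population almost always
carries `b^0 = b^5 = 1`), the interior leans defective, and the two most
visited strategies are the All-Or-None rule with either opening move —
the population cooperates about 74% of the time even though a one-shot
group would collapse to full defection (`F/N = 0.85 < 1`).

The same analyses are available from the shell:

```bash
reactivepgg bits --N 5 --Z 100 --beta 1.0 --F-over-N 0.85 --w 0.96 --eps 0.05
reactivepgg gradient --pair AoN:AllD --first-move 0 --N 5 --F-over-N 0.85 --w 0.96 --eps 0.05 --Z 100
reactivepgg sweep --parameter eps --grid 0.0:0.3:0.01 --N 5 --F-over-N 0.85 --w 0.96 --Z 100
reactivepgg abm --N 2 --Z 30 --F-over-N 0.85 --w 0.96 --eps 0.05 --mu 1e-3 --events 1000000 --seed 1
```

Each run writes CSV tables plus a JSON manifest (full configuration,
seed, version, runtime) sufficient to regenerate it.

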