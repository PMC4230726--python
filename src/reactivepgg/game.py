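"""Exact repeated public goods game for groups drawn from two behavior profiles.

A group of ``N`` players repeats the one-shot N-person prisoner's dilemma:
each round every player contributes ``c`` (cooperates) or not, the pot is
multiplied by the enhancement factor ``F`` and split equally, and another
round follows with probability ``w`` (mean number of rounds
``m = 1/(1-w)``).  Intended acts are flipped by an execution error with
probability ``eps``.

Because payoffs are linear in the number of contributors and all players
sharing a profile behave exchangeably, the exact per-round dynamics reduce
to a Markov chain on the total cooperator count q in {0..N}.  The chain is
assembled row by row from sums of independent binomials, and the
discounted round occupancy has the closed form ``(1-w) v0 (I - wM)^-1``.
A seeded Monte Carlo playout serves as the stochastic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .strategies import BehaviorProfile, Strategy

__all__ = [
    "GameParams",
    "GroupComposition",
    "RoundChain",
    "single_round_payoffs",
    "round_transition",
    "build_round_chain",
    "discounted_round_averages",
    "expected_group_payoff",
    "simulate_group_playout",
    "simulate_many_playouts",
]


@dataclass(frozen=True)
class GameParams:
    """One repeated-PGG environment.

    Parameters
    ----------
    N : group size.
    F : enhancement factor multiplying the pot (dimensionless).
    c : contribution cost, payoff units (all payoffs scale linearly in c).
    w : continuation probability in [0, 1); mean rounds m = 1/(1-w).
    eps : execution-error probability in [0, 0.5].
    """

    N: int
    F: float
    c: float = 1.0
    w: float = 0.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not 0.0 <= self.w < 1.0:
            raise ValueError(f"w must be in [0, 1), got {self.w}")
        if not 0.0 <= self.eps <= 0.5:
            raise ValueError(f"eps must be in [0, 0.5], got {self.eps}")
        if self.F < 0:
            raise ValueError(f"F must be nonnegative, got {self.F}")

    @classmethod
    def from_f_over_n(
        cls, N: int, f_over_n: float, c: float = 1.0, w: float = 0.0, eps: float = 0.0
    ) -> "GameParams":
        """Build params from the ratio F/N (e.g. F/N = 0.85, N = 5 -> F = 4.25)."""
        return cls(N=N, F=f_over_n * N, c=c, w=w, eps=eps)

    @property
    def m(self) -> float:
        """Mean number of rounds, 1/(1-w)."""
        return 1.0 / (1.0 - self.w)

    def with_eps(self, eps: float) -> "GameParams":
        return replace(self, eps=eps)


@dataclass(frozen=True)
class GroupComposition:
    """Split of an N-player group between profile A (n_a) and profile B."""

    N: int
    n_a: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_a <= self.N:
            raise ValueError(f"n_a must be in [0, {self.N}], got {self.n_a}")

    @property
    def n_b(self) -> int:
        return self.N - self.n_a


@dataclass(frozen=True)
class RoundChain:
    """Markov chain on the cooperator count with initial distribution v0."""

    N: int
    M: np.ndarray = field(repr=False)  # (N+1, N+1) row-stochastic
    v0: np.ndarray = field(repr=False)  # first-round count distribution


def _as_profile(s: Strategy | BehaviorProfile, eps: float) -> BehaviorProfile:
    if isinstance(s, Strategy):
        return s.profile(eps)
    return s


def single_round_payoffs(k: int, params: GameParams) -> tuple[float, float]:
    """One-shot payoffs (defector, cooperator) when k of N contribute.

    The pot F*c*k is split over all N players; a cooperator additionally
    paid its contribution c.  k counts every contribution in the round,
    including the focal cooperator's own.
    """
    if not 0 <= k <= params.N:
        raise ValueError(f"k must be in [0, {params.N}], got {k}")
    share = params.F * params.c * k / params.N
    return share, share - params.c


def _count_pmf(n_a: int, p_a: float, n_b: int, p_b: float) -> np.ndarray:
    """PMF of Binomial(n_a, p_a) + Binomial(n_b, p_b) over {0..n_a+n_b}."""
    pa = binom.pmf(np.arange(n_a + 1), n_a, p_a)
    pb = binom.pmf(np.arange(n_b + 1), n_b, p_b)
    return np.convolve(pa, pb)


def round_transition(
    q: int,
    profile_a: Strategy | BehaviorProfile,
    profile_b: Strategy | BehaviorProfile,
    comp: GroupComposition,
    params: GameParams,
) -> np.ndarray:
    """Distribution of the next cooperator count given q in the previous round.

    Given the observation q, each A-player cooperates independently with
    probability p_A(q) (error rate already applied) and likewise for B, so
    the next count is Binomial(n_a, p_A(q)) + Binomial(n_b, p_B(q)).
    """
    if not 0 <= q <= params.N:
        raise ValueError(f"q must be in [0, {params.N}], got {q}")
    a = _as_profile(profile_a, params.eps)
    b = _as_profile(profile_b, params.eps)
    if a.N != params.N or b.N != params.N or comp.N != params.N:
        raise ValueError("profiles, composition and params must share the same N")
    return _count_pmf(comp.n_a, a.p_after[q], comp.n_b, b.p_after[q])


def build_round_chain(
    profile_a: Strategy | BehaviorProfile,
    profile_b: Strategy | BehaviorProfile,
    comp: GroupComposition,
    params: GameParams,
) -> RoundChain:
    """Assemble the count chain: rows from round_transition, v0 from b^-1."""
    a = _as_profile(profile_a, params.eps)
    b = _as_profile(profile_b, params.eps)
    N = params.N
    M = np.empty((N + 1, N + 1))
    for q in range(N + 1):
        M[q] = _count_pmf(comp.n_a, a.p_after[q], comp.n_b, b.p_after[q])
    v0 = _count_pmf(comp.n_a, a.p_initial, comp.n_b, b.p_initial)
    return RoundChain(N=N, M=M, v0=v0)


def discounted_round_averages(chain: RoundChain, params: GameParams) -> np.ndarray:
    """Discounted long-run occupancy over cooperator counts.

    u = (1-w) * sum_t w^t v0 M^t = (1-w) v0 (I - wM)^-1; u_q is the
    discounted fraction of rounds spent at count q and u sums to 1.
    """
    w = params.w
    A = np.eye(chain.N + 1) - w * chain.M
    u = (1.0 - w) * np.linalg.solve(A.T, chain.v0)
    return u


def expected_group_payoff(
    profile_a: Strategy | BehaviorProfile,
    profile_b: Strategy | BehaviorProfile,
    comp: GroupComposition,
    params: GameParams,
) -> tuple[float, float, float]:
    """Exact per-round expected payoffs (pi_A, pi_B) and cooperation rate.

    Payoffs are averaged over rounds with the discounted occupancy.  In a
    round following observation q an A-player cooperates with probability
    p_A(q) and earns F*c*(n_a p_A(q) + n_b p_B(q))/N - c*p_A(q); linearity
    in the count means only these means are needed.  The round-1 term uses
    the opening probabilities.  pi_A is NaN when n_a = 0 (likewise pi_B).

    coop_rate is the expected fraction of cooperative acts per round.
    """
    a = _as_profile(profile_a, params.eps)
    b = _as_profile(profile_b, params.eps)
    chain = build_round_chain(a, b, comp, params)
    u = discounted_round_averages(chain, params)
    N, w, F, c = params.N, params.w, params.F, params.c
    counts = np.arange(N + 1, dtype=float)
    mean_count = float(u @ counts)  # discounted mean contributions per round
    coop_rate = mean_count / N

    def per_player(profile: BehaviorProfile, n_self: int) -> float:
        if n_self == 0:
            return float("nan")
        # discounted P(this player's act is cooperative): round 1 carries
        # weight (1-w); rounds >= 2 condition on the previous count, whose
        # discounted distribution is u shifted one round (weight w).
        p_coop = (1.0 - w) * profile.p_initial + w * float(u @ profile.p_after)
        return F * c * mean_count / N - c * p_coop

    return per_player(a, comp.n_a), per_player(b, comp.n_b), coop_rate


def simulate_group_playout(
    profile_a: Strategy | BehaviorProfile,
    profile_b: Strategy | BehaviorProfile,
    comp: GroupComposition,
    params: GameParams,
    rng: np.random.Generator,
) -> tuple[float, float, np.ndarray]:
    """One stochastic playout of the repeated game.

    The number of rounds is geometric with mean m = 1/(1-w); each player's
    act is drawn with the error rate folded in.  Returns the per-round
    average payoff of an A-player and of a B-player (NaN if absent) and the
    per-round cooperator-count trace.
    """
    tot_a, tot_b, counts = simulate_many_playouts(
        profile_a, profile_b, comp, params, n_playouts=1, rng=rng, keep_trace=True
    )
    rounds = counts.shape[1]
    avg_a = float(tot_a[0]) / rounds if comp.n_a else float("nan")
    avg_b = float(tot_b[0]) / rounds if comp.n_b else float("nan")
    return avg_a, avg_b, counts[0]


def simulate_many_playouts(
    profile_a: Strategy | BehaviorProfile,
    profile_b: Strategy | BehaviorProfile,
    comp: GroupComposition,
    params: GameParams,
    n_playouts: int,
    rng: np.random.Generator,
    keep_trace: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized playouts; the Monte Carlo oracle for the exact engine.

    Returns (total payoff of one A-player per playout, same for B, count
    trace).  Totals are per-round sums over the realized rounds; pair them
    with the realized round numbers via the trace, or use the ratio of
    means E[total]/E[rounds], which estimates the discounted expectation.
    The trace is a (n_playouts, max_rounds) array of cooperator counts,
    -1 past each playout's last round (only if keep_trace).
    """
    a = _as_profile(profile_a, params.eps)
    b = _as_profile(profile_b, params.eps)
    N, w = params.N, params.w
    n_a, n_b = comp.n_a, comp.n_b
    F, c = params.F, params.c
    # rounds ~ 1 + Geometric(1-w) support {1, 2, ...}
    if w == 0.0:
        T = np.ones(n_playouts, dtype=np.int64)
    else:
        T = rng.geometric(1.0 - w, size=n_playouts)
    t_max = int(T.max())
    tot_a = np.zeros(n_playouts)
    tot_b = np.zeros(n_playouts)
    trace = np.full((n_playouts, t_max), -1, dtype=np.int64) if keep_trace else None

    pa_after, pb_after = a.p_after, b.p_after
    # round 1
    active = np.arange(n_playouts)
    ca = rng.binomial(n_a, a.p_initial, size=n_playouts)
    cb = rng.binomial(n_b, b.p_initial, size=n_playouts)
    for t in range(t_max):
        if t > 0:
            alive = T[active] > t
            active = active[alive]
            if active.size == 0:
                break
            q = k[alive]  # previous-round counts of still-active playouts
            ca = rng.binomial(n_a, pa_after[q])
            cb = rng.binomial(n_b, pb_after[q])
        k = ca + cb
        share = F * c * k / N
        if n_a:
            tot_a[active] += share - c * ca / n_a
        if n_b:
            tot_b[active] += share - c * cb / n_b
        if keep_trace:
            trace[active, t] = k
    if trace is None:
        trace = np.empty((n_playouts, 0), dtype=np.int64)
    return tot_a, tot_b, trace
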