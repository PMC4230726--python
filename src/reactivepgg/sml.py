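"""Small-mutation-limit analysis over monomorphic strategy states.

When mutations are rare (mu << 1/Z) the population is monomorphic almost
always, and a mutant either dies out or fixes before the next mutation
arrives.  Evolution then reduces to an embedded Markov chain whose states
are the available strategies and whose transitions are single-mutant
fixation probabilities divided by the number of alternative strategies.
The stationary distribution tau gives the fraction of time spent in each
monomorphic state; from it follow the stationary bit distribution
B^q = sum_i tau_i b_i^q, the dominant-bit classification and the level of
cooperation eta = sum_i tau_i C_i / N.

The full space holds 2^(N+2) strategies, so the pipeline needs all ordered
pairwise fixation probabilities.  The fast path below exploits that a pure
strategy's per-act cooperation probability is either eps or 1-eps: at a
fixed group composition there are only four distinct transition rows (one
per ordered bit pair), so every pair's round chain is assembled by indexing
into four precomputed rows and all chains are solved in one batched linear
solve.  The generic per-pair route through the game engine remains
available (and is the one mixed-profile subsets use); the two are asserted
equal in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .dynamics import (
    PairPayoffTable,
    PopulationParams,
    fixation_probability,
    group_sampling_weights,
)
from .game import GameParams, GroupComposition, expected_group_payoff
from .strategies import BehaviorProfile, Strategy, bits_matrix, decode_strategy

__all__ = [
    "SMLResult",
    "DominanceCall",
    "PairData",
    "embedded_transition_matrix",
    "stationary_distribution",
    "stationary_bit_distribution",
    "classify_dominant_bits",
    "monomorphic_cooperation_rate",
    "level_of_cooperation",
    "run_sml",
    "sweep",
]

Profile = Union[Strategy, BehaviorProfile]

_SOLVE_CHUNK = 200_000  # pairs per batched linear solve, caps peak memory


# ---------------------------------------------------------------------------
# batched pure-strategy pair payoffs


@dataclass(frozen=True)
class PairData:
    """All unordered-pair quantities from the batched pipeline.

    Arrays are indexed by pair p = (i_idx[p], j_idx[p]) with i < j over the
    strategy set; payoff arrays have one column per composition n_a = 0..N
    (pi_a NaN-free but meaningless at n_a = 0, likewise pi_b at n_a = N).
    f_a/f_b are fitness at k = 1..Z-1 A-players; rho_a is the fixation
    probability of a single A-mutant in a B-resident population, rho_b the
    reverse.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray
    pi_a: np.ndarray
    pi_b: np.ndarray
    coop: np.ndarray
    f_a: np.ndarray
    f_b: np.ndarray
    rho_a: np.ndarray
    rho_b: np.ndarray


def _pair_payoff_arrays(
    bits: np.ndarray, params: GameParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact pair payoffs for every unordered pair of pure strategies.

    bits: (n, N+2) 0/1 matrix in set order.  Returns (i_idx, j_idx, pi_a,
    pi_b, coop) with payoff arrays of shape (n_pairs, N+1) over n_a.
    """
    n, width = bits.shape
    N = width - 2
    eps, w, F, c = params.eps, params.w, params.F, params.c
    p_of_bit = np.array([eps, 1.0 - eps])

    i_idx, j_idx = np.triu_indices(n, k=1)
    n_pairs = i_idx.size
    # per (pair, observation) row code 2*b_A + b_B selects one of 4 rows
    codes_obs = (2 * bits[i_idx, 1:] + bits[j_idx, 1:]).astype(np.intp)
    codes_init = (2 * bits[i_idx, 0] + bits[j_idx, 0]).astype(np.intp)
    p_a_obs = p_of_bit[bits[i_idx, 1:]]  # (n_pairs, N+1)
    p_b_obs = p_of_bit[bits[j_idx, 1:]]
    p_a_init = p_of_bit[bits[i_idx, 0]]
    p_b_init = p_of_bit[bits[j_idx, 0]]

    counts = np.arange(N + 1, dtype=float)
    pi_a = np.empty((n_pairs, N + 1))
    pi_b = np.empty((n_pairs, N + 1))
    coop = np.empty((n_pairs, N + 1))

    # binomial pmfs for every (trial count, bit value)
    pmf = {
        (m, b): binom.pmf(np.arange(m + 1), m, p_of_bit[b])
        for m in range(N + 1)
        for b in (0, 1)
    }
    eye = np.eye(N + 1)
    for n_a in range(N + 1):
        n_b = N - n_a
        rows = np.empty((4, N + 1))
        for b_a in (0, 1):
            for b_b in (0, 1):
                rows[2 * b_a + b_b] = np.convolve(pmf[(n_a, b_a)], pmf[(n_b, b_b)])
        for lo in range(0, n_pairs, _SOLVE_CHUNK):
            sl = slice(lo, min(lo + _SOLVE_CHUNK, n_pairs))
            M = rows[codes_obs[sl]]  # (chunk, N+1, N+1)
            v0 = rows[codes_init[sl]]  # (chunk, N+1)
            A = eye[None, :, :] - w * np.swapaxes(M, 1, 2)
            r = np.linalg.solve(A, v0[:, :, None])[:, :, 0]
            u = (1.0 - w) * r  # discounted occupancy over counts
            mean_count = u @ counts
            p_coop_a = (1.0 - w) * p_a_init[sl] + w * (u * p_a_obs[sl]).sum(axis=1)
            p_coop_b = (1.0 - w) * p_b_init[sl] + w * (u * p_b_obs[sl]).sum(axis=1)
            pi_a[sl, n_a] = F * c * mean_count / N - c * p_coop_a
            pi_b[sl, n_a] = F * c * mean_count / N - c * p_coop_b
            coop[sl, n_a] = mean_count / N
    return i_idx, j_idx, pi_a, pi_b, coop


def _monomorphic_arrays(
    bits: np.ndarray, params: GameParams
) -> tuple[np.ndarray, np.ndarray]:
    """(payoff, cooperation rate) of each pure strategy in its own group."""
    n, width = bits.shape
    N = width - 2
    eps, w, F, c = params.eps, params.w, params.F, params.c
    p_of_bit = np.array([eps, 1.0 - eps])
    pmf = np.stack(
        [binom.pmf(np.arange(N + 1), N, p_of_bit[b]) for b in (0, 1)]
    )  # (2, N+1)
    M = pmf[bits[:, 1:]]  # (n, N+1, N+1)
    v0 = pmf[bits[:, 0]]  # (n, N+1)
    A = np.eye(N + 1)[None, :, :] - w * np.swapaxes(M, 1, 2)
    u = (1.0 - w) * np.linalg.solve(A, v0[:, :, None])[:, :, 0]
    counts = np.arange(N + 1, dtype=float)
    mean_count = u @ counts
    p_obs = p_of_bit[bits[:, 1:]]
    p_coop = (1.0 - w) * p_of_bit[bits[:, 0]] + w * (u * p_obs).sum(axis=1)
    return F * c * mean_count / N - c * p_coop, mean_count / N


def _pairwise_fixation(
    pi_a: np.ndarray, pi_b: np.ndarray, N: int, pop: PopulationParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fitness and both-direction fixation probabilities for all pairs."""
    Z, beta = pop.Z, pop.beta
    H_a, H_b = group_sampling_weights(Z, N)
    f_a = pi_a[:, 1:] @ H_a.T  # (n_pairs, Z-1), k = 1..Z-1 A-players
    f_b = pi_b[:, :N] @ H_b.T
    D = beta * (f_a - f_b)
    zeros = np.zeros((D.shape[0], 1))
    # A-mutant in B-residents: log T-/T+ at j A-players is -D[:, j-1]
    cum_a = np.concatenate([zeros, np.cumsum(-D, axis=1)], axis=1)
    rho_a = np.exp(-logsumexp(cum_a, axis=1))
    # B-mutant in A-residents: j B-players means Z-j A-players
    cum_b = np.concatenate([zeros, np.cumsum(D[:, ::-1], axis=1)], axis=1)
    rho_b = np.exp(-logsumexp(cum_b, axis=1))
    return f_a, f_b, rho_a, rho_b


def compute_pair_data(
    bits: np.ndarray, params: GameParams, pop: PopulationParams
) -> PairData:
    """Run the batched pair pipeline: payoffs, fitness, fixation."""
    i_idx, j_idx, pi_a, pi_b, coop = _pair_payoff_arrays(bits, params)
    f_a, f_b, rho_a, rho_b = _pairwise_fixation(pi_a, pi_b, params.N, pop)
    return PairData(i_idx, j_idx, pi_a, pi_b, coop, f_a, f_b, rho_a, rho_b)


# ---------------------------------------------------------------------------
# embedded chain and stationary statistics


def _is_pure_set(strategy_set: Sequence[Profile]) -> bool:
    return all(isinstance(s, Strategy) for s in strategy_set)


def _set_bits(strategy_set: Sequence[Profile]) -> np.ndarray:
    """Per-strategy intent matrix: bits for pure strategies, cooperation
    probabilities for behavior profiles (e.g. 0.5 throughout for RS)."""
    rows = []
    for s in strategy_set:
        if isinstance(s, Strategy):
            rows.append(np.asarray(s.bits, dtype=float))
        else:
            rows.append(np.asarray(s.coop_prob, dtype=float))
    return np.vstack(rows)


def embedded_transition_matrix(
    strategy_set: Sequence[Profile],
    game_params: GameParams,
    pop: PopulationParams,
    pair_data: PairData | None = None,
) -> np.ndarray:
    """Row-stochastic transition matrix of the small-mutation-limit chain.

    Lambda[i, j] = rho(j invades monomorphic i) / (|S| - 1) off-diagonal;
    diagonal takes the complement.  Pure-strategy sets use the batched
    pipeline; sets containing behavior profiles fall back to per-pair
    tables from the game engine.
    """
    n = len(strategy_set)
    if n < 2:
        raise ValueError("need at least two strategies")
    L = np.zeros((n, n))
    if _is_pure_set(strategy_set):
        if pair_data is None:
            bits = np.array([s.bits for s in strategy_set], dtype=np.int8)
            pair_data = compute_pair_data(bits, game_params, pop)
        L[pair_data.j_idx, pair_data.i_idx] = pair_data.rho_a
        L[pair_data.i_idx, pair_data.j_idx] = pair_data.rho_b
    else:
        for i in range(n):
            for j in range(i + 1, n):
                table = PairPayoffTable.build(
                    strategy_set[i], strategy_set[j], game_params
                )
                L[j, i] = fixation_probability(
                    strategy_set[i], strategy_set[j], game_params, pop, table=table
                )
                L[i, j] = fixation_probability(
                    strategy_set[j], strategy_set[i], game_params, pop,
                    table=table.swapped(),
                )
    L /= n - 1
    np.fill_diagonal(L, 0.0)
    np.fill_diagonal(L, 1.0 - L.sum(axis=1))
    return L


def stationary_distribution(L: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unique left fixed vector of a row-stochastic irreducible matrix.

    Solved as the linear system tau (L - I) = 0 with the normalization
    constraint appended (least squares), not by power iteration.  Raises if
    the fixed-point residual exceeds ``tol``.
    """
    n = L.shape[0]
    A = np.vstack([L.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    tau, *_ = np.linalg.lstsq(A, b, rcond=None)
    tau = np.clip(tau, 0.0, None)
    tau /= tau.sum()
    resid = float(np.max(np.abs(tau @ L - tau)))
    if resid > tol:
        raise np.linalg.LinAlgError(
            f"stationary distribution residual {resid:.3e} exceeds {tol:.1e}"
        )
    return tau


def stationary_bit_distribution(
    tau: np.ndarray, strategy_set: Sequence[Profile]
) -> np.ndarray:
    """B^q = sum_i tau_i b_i^q over bit positions q = -1, 0, ..., N."""
    return tau @ _set_bits(strategy_set)


@dataclass(frozen=True)
class DominanceCall:
    """Per-bit dominance labels under thresholds (hi, lo)."""

    labels: tuple[str, ...]  # cooperative / defective / undecided per position
    hi: float
    lo: float


def classify_dominant_bits(
    bit_dist: np.ndarray, hi: float = 0.75, lo: float = 0.25
) -> DominanceCall:
    """Label each bit position by where its stationary value falls.

    A bit carrying the same value more than 75% of the time (defaults) is
    dominant: cooperative if B^q >= hi, defective if B^q <= lo.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    labels = tuple(
        "cooperative" if v >= hi else "defective" if v <= lo else "undecided"
        for v in np.asarray(bit_dist, dtype=float)
    )
    return DominanceCall(labels=labels, hi=hi, lo=lo)


def monomorphic_cooperation_rate(
    strategy: Profile, game_params: GameParams
) -> float:
    """C_i / N: discounted contributions per round in a monomorphic group,
    normalized by the group size."""
    comp = GroupComposition(N=game_params.N, n_a=game_params.N)
    _, _, coop = expected_group_payoff(strategy, strategy, comp, game_params)
    return coop


def level_of_cooperation(tau: np.ndarray, coop_rates: np.ndarray) -> float:
    """eta = sum_i tau_i C_i / N, the stationary cooperation level."""
    return float(np.asarray(tau) @ np.asarray(coop_rates))


@dataclass(frozen=True)
class SMLResult:
    """Stationary distribution over monomorphic states plus derived stats.

    tau is set-relative: over a configured subset it describes the
    restricted chain, not the full strategy space.
    """

    strategy_set: tuple[Profile, ...]
    tau: np.ndarray
    bit_dist: np.ndarray  # positions b^-1, b^0 .. b^N
    coop_rates: np.ndarray  # per-strategy monomorphic C_i / N
    eta: float
    game_params: GameParams
    pop: PopulationParams
    pair_data: PairData | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.game_params.N

    def dominance(self, hi: float = 0.75, lo: float = 0.25) -> DominanceCall:
        return classify_dominant_bits(self.bit_dist, hi=hi, lo=lo)

    def top_strategies(self, n: int = 10) -> pd.DataFrame:
        return self.to_strategy_frame().nlargest(n, "tau")

    def to_strategy_frame(self) -> pd.DataFrame:
        labels = [
            s.to_string() if isinstance(s, Strategy) else "RS"
            for s in self.strategy_set
        ]
        ids = [
            s.id if isinstance(s, Strategy) else -1 for s in self.strategy_set
        ]
        return pd.DataFrame(
            {
                "id": ids,
                "strategy": labels,
                "tau": self.tau,
                "coop_rate": self.coop_rates,
            }
        )

    def to_bit_frame(self, hi: float = 0.75, lo: float = 0.25) -> pd.DataFrame:
        call = self.dominance(hi=hi, lo=lo)
        return pd.DataFrame(
            {
                "q": list(range(-1, self.N + 1)),
                "B": self.bit_dist,
                "call": list(call.labels),
            }
        )


def run_sml(
    game_params: GameParams,
    pop: PopulationParams,
    strategy_set: Sequence[Profile] | None = None,
    keep_pair_data: bool = False,
) -> SMLResult:
    """Full small-mutation-limit pipeline.

    With ``strategy_set=None`` the chain runs over all 2^(N+2) reactive
    strategies.  ``keep_pair_data`` retains the batched pair fitness tables
    (pure sets only) for reuse, e.g. by the agent-based simulator.
    """
    if strategy_set is None:
        strategy_set = [
            decode_strategy(i, game_params.N) for i in range(1 << (game_params.N + 2))
        ]
    strategy_set = tuple(strategy_set)
    pair_data: PairData | None = None
    if _is_pure_set(strategy_set):
        bits = np.array([s.bits for s in strategy_set], dtype=np.int8)
        pair_data = compute_pair_data(bits, game_params, pop)
        L = embedded_transition_matrix(strategy_set, game_params, pop, pair_data)
        _, coop_rates = _monomorphic_arrays(bits, game_params)
    else:
        L = embedded_transition_matrix(strategy_set, game_params, pop)
        coop_rates = np.array(
            [monomorphic_cooperation_rate(s, game_params) for s in strategy_set]
        )
    tau = stationary_distribution(L)
    bit_dist = stationary_bit_distribution(tau, strategy_set)
    eta = level_of_cooperation(tau, coop_rates)
    return SMLResult(
        strategy_set=strategy_set,
        tau=tau,
        bit_dist=bit_dist,
        coop_rates=coop_rates,
        eta=eta,
        game_params=game_params,
        pop=pop,
        pair_data=pair_data if keep_pair_data else None,
    )


def sweep(
    parameter: str,
    grid: Sequence[float],
    game_params: GameParams,
    pop: PopulationParams,
    strategy_set: Sequence[Profile] | None = None,
    f_over_n: float | None = None,
) -> pd.DataFrame:
    """Rerun the SML pipeline along a grid of one parameter.

    ``parameter`` is one of N, eps, w, F (or m, mapped to w = 1 - 1/m).
    When sweeping N, pass ``f_over_n`` to hold the ratio F/N fixed across
    group sizes (the convention of the group-size analysis); otherwise F is
    held constant.  One summary row per grid point: bit distribution
    columns B_-1..B_N and the cooperation level eta.  Per-point failures
    are recorded in the ``error`` column and the sweep continues.
    """
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    if parameter not in {"N", "eps", "w", "F", "m"}:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    rows = []
    for value in grid:
        row: dict[str, object] = {parameter: value}
        try:
            gp = _with_parameter(game_params, parameter, value, f_over_n)
            sset = None if parameter == "N" else strategy_set
            res = run_sml(gp, pop, strategy_set=sset)
            for q, bq in zip(range(-1, gp.N + 1), res.bit_dist):
                row[f"B_{q}"] = bq
            row["eta"] = res.eta
        except Exception as exc:  # pragma: no cover - defensive
            row["error"] = repr(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _with_parameter(
    gp: GameParams, parameter: str, value: float, f_over_n: float | None = None
) -> GameParams:
    if parameter == "N":
        F = f_over_n * int(value) if f_over_n is not None else gp.F
        return GameParams(N=int(value), F=F, c=gp.c, w=gp.w, eps=gp.eps)
    if parameter == "eps":
        return gp.with_eps(float(value))
    if parameter == "w":
        return GameParams(N=gp.N, F=gp.F, c=gp.c, w=float(value), eps=gp.eps)
    if parameter == "m":
        if value < 1:
            raise ValueError("mean rounds m must be >= 1")
        return GameParams(N=gp.N, F=gp.F, c=gp.c, w=1.0 - 1.0 / float(value), eps=gp.eps)
    return GameParams(N=gp.N, F=float(value), c=gp.c, w=gp.w, eps=gp.eps)
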