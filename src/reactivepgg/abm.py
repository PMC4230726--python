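"""Agent-based birth-death simulation at finite mutation rates.

Validates the small-mutation-limit analytics: a population of Z
individuals evolves by asynchronous events — pick a focal individual
uniformly; with probability mu it adopts a uniformly random strategy from
the set, otherwise it imitates a random other member under the Fermi rule.
Time averages of strategy and bit frequencies after burn-in are compared
with the stationary distribution of the embedded chain.

Fitness defaults to the exact expected payoff given the current population
composition.  When at most two strategies are present (the typical state
when mu*Z is small and the run starts monomorphic) fitness comes from
precomputed all-pairs tables; with three or more coexisting strategies an
exact multivariate-hypergeometric average over group compositions is
computed and cached.  A sampled-playouts mode estimates fitness from
stochastic game playouts instead, for full-stochastic validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence, Union

import numpy as np

from .dynamics import PairPayoffTable, PopulationParams, fitness_profile
from .game import GameParams, GroupComposition, simulate_many_playouts
from .sml import PairData, SMLResult, _monomorphic_arrays, _set_bits, compute_pair_data
from .strategies import BehaviorProfile, Strategy, decode_strategy

__all__ = ["ABMConfig", "ABMResult", "ComparisonReport", "run_abm", "compare_abm_sml"]

Profile = Union[Strategy, BehaviorProfile]

_BLOCK = 1 << 15  # random numbers pre-drawn per chunk of events


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of one agent-based run.

    ``n_events`` counts individual update events (one focal per event; a
    generation in the reporting sense is Z events).  ``fitness_mode`` is
    ``"analytic"`` (exact expected payoff given the composition, default)
    or ``"sampled"`` (Monte Carlo playouts over ``n_sample_groups`` groups
    per evaluation).  The seed is mandatory: runs are bit-reproducible.
    """

    game_params: GameParams
    pop: PopulationParams
    n_events: int
    seed: int
    burn_in: int = 0
    strategy_set: tuple[Profile, ...] | None = None
    fitness_mode: str = "analytic"
    n_sample_groups: int = 32
    n_blocks: int = 10
    init: str = "random-monomorphic"  # or "uniform"

    def __post_init__(self) -> None:
        if self.pop.mu <= 0.0:
            raise ValueError("ABM requires a positive mutation rate mu")
        if not 0 <= self.burn_in < self.n_events:
            raise ValueError("need 0 <= burn_in < n_events")
        if self.fitness_mode not in ("analytic", "sampled"):
            raise ValueError(f"unknown fitness mode {self.fitness_mode!r}")
        if self.init not in ("random-monomorphic", "uniform"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 averaging blocks")


@dataclass(frozen=True)
class ABMResult:
    """Time averages from one run (weights: one unit per post-burn-in event)."""

    config: ABMConfig
    strategy_freq: np.ndarray  # (n_set,) time-averaged frequencies
    bit_freq: np.ndarray  # (N+2,) time-averaged bit/intent frequencies
    block_strategy_freq: np.ndarray = field(repr=False)  # (n_blocks, n_set)
    cooperation: float = 0.0  # freq-weighted monomorphic cooperation rate
    n_mutations: int = 0
    n_switches: int = 0

    @property
    def block_bit_freq(self) -> np.ndarray:
        bits = _set_bits(_resolved_set(self.config))
        return self.block_strategy_freq @ bits

    @property
    def bit_se(self) -> np.ndarray:
        """Per-bit standard error from block means."""
        b = self.block_bit_freq
        return b.std(axis=0, ddof=1) / np.sqrt(b.shape[0])


def _resolved_set(config: ABMConfig) -> tuple[Profile, ...]:
    if config.strategy_set is not None:
        return tuple(config.strategy_set)
    N = config.game_params.N
    return tuple(decode_strategy(i, N) for i in range(1 << (N + 2)))


class _FitnessTables:
    """Pairwise fitness lookups plus an exact multi-type fallback."""

    def __init__(
        self,
        strategy_set: Sequence[Profile],
        game_params: GameParams,
        pop: PopulationParams,
        pair_data: PairData | None = None,
    ) -> None:
        self.set = tuple(strategy_set)
        self.n = len(self.set)
        self.gp = game_params
        self.pop = pop
        self.profiles = [
            s.profile(game_params.eps) if isinstance(s, Strategy) else s
            for s in self.set
        ]
        pure = all(isinstance(s, Strategy) for s in self.set)
        if pure:
            bits = np.array([s.bits for s in self.set], dtype=np.int8)
            if pair_data is None:
                pair_data = compute_pair_data(bits, game_params, pop)
            self.f_a, self.f_b = pair_data.f_a, pair_data.f_b
        else:
            n_pairs = self.n * (self.n - 1) // 2
            self.f_a = np.empty((n_pairs, pop.Z - 1))
            self.f_b = np.empty((n_pairs, pop.Z - 1))
            p = 0
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    table = PairPayoffTable.build(self.set[i], self.set[j], game_params)
                    self.f_a[p], self.f_b[p] = fitness_profile(table, pop.Z)
                    p += 1
        self._group_cache: dict[tuple, float] = {}

    def _pair_index(self, i: int, j: int) -> int:
        # row-major upper-triangle (k=1) index for i < j
        return i * self.n - i * (i + 1) // 2 + (j - i - 1)

    def two_type(self, i: int, j: int, k_i: int) -> tuple[float, float]:
        """(f_i, f_j) when k_i hold strategy i and Z-k_i hold j (i != j)."""
        if i < j:
            p = self._pair_index(i, j)
            return float(self.f_a[p, k_i - 1]), float(self.f_b[p, k_i - 1])
        p = self._pair_index(j, i)
        k_j = self.pop.Z - k_i
        return float(self.f_b[p, k_j - 1]), float(self.f_a[p, k_j - 1])

    def exact_multi(self, focal: int, counts: dict[int, int]) -> float:
        """Exact fitness of set-member ``focal`` in an arbitrary composition.

        Averages the focal's exact group payoff over all compositions of
        its N-1 co-players, drawn without replacement from the other Z-1
        individuals (multivariate hypergeometric).
        """
        N, Z = self.gp.N, self.pop.Z
        others = dict(counts)
        others[focal] = others.get(focal, 0) - 1
        others = {t: c for t, c in others.items() if c > 0}
        types = sorted(others)
        total = comb(Z - 1, N - 1)
        f = 0.0
        for alloc in _compositions(N - 1, [others[t] for t in types]):
            weight = 1
            for t, g in zip(types, alloc):
                weight *= comb(others[t], g)
            # group composition including the focal player
            comp: dict[int, int] = {}
            for t, g in zip(types, alloc):
                if g:
                    comp[t] = comp.get(t, 0) + g
            comp[focal] = comp.get(focal, 0) + 1
            f += weight / total * self._group_payoff(focal, tuple(sorted(comp.items())))
        return f

    def _group_payoff(self, focal: int, comp_key: tuple[tuple[int, int], ...]) -> float:
        cached = self._group_cache.get((focal, comp_key))
        if cached is not None:
            return cached
        N, w = self.gp.N, self.gp.w
        F, c = self.gp.F, self.gp.c
        # chain over cooperator counts; rows are Poisson-binomial pmfs built
        # by convolving one binomial per strategy type in the group
        M = np.empty((N + 1, N + 1))
        for q in range(N + 1):
            M[q] = _multi_count_pmf(
                [(self.profiles[t].p_after[q], cnt) for t, cnt in comp_key], N
            )
        v0 = _multi_count_pmf(
            [(self.profiles[t].p_initial, cnt) for t, cnt in comp_key], N
        )
        A = np.eye(N + 1) - w * M
        u = (1.0 - w) * np.linalg.solve(A.T, v0)
        mean_count = float(u @ np.arange(N + 1))
        prof = self.profiles[focal]
        p_coop = (1.0 - w) * prof.p_initial + w * float(u @ prof.p_after)
        payoff = F * c * mean_count / N - c * p_coop
        self._group_cache[(focal, comp_key)] = payoff
        return payoff


def _multi_count_pmf(parts: Sequence[tuple[float, int]], N: int) -> np.ndarray:
    """PMF of a sum of independent binomials, padded to length N+1."""
    pmf = np.array([1.0])
    for p, n in parts:
        if n == 0:
            continue
        ks = np.arange(n + 1)
        b = np.array([comb(n, k) for k in ks]) * p**ks * (1 - p) ** (n - ks)
        pmf = np.convolve(pmf, b)
    out = np.zeros(N + 1)
    out[: pmf.size] = pmf
    return out


def _compositions(total: int, caps: Sequence[int]):
    """All allocations of ``total`` items over bins with capacities ``caps``."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for g in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - g, caps[1:]):
            yield (g,) + rest


def run_abm(config: ABMConfig, pair_data: PairData | None = None) -> ABMResult:
    """Run the event loop; fully reproducible from the config seed.

    ``pair_data`` may pass in the batched pair tables from an SML run over
    the same strategy set and parameters to skip recomputing them.
    """
    strategy_set = _resolved_set(config)
    n_set = len(strategy_set)
    if n_set < 2:
        raise ValueError("need at least two strategies")
    gp, pop = config.game_params, config.pop
    Z, beta, mu = pop.Z, pop.beta, pop.mu
    rng = np.random.default_rng(config.seed)

    tables = _FitnessTables(strategy_set, gp, pop, pair_data=pair_data)
    sampled = config.fitness_mode == "sampled"

    # population state
    if config.init == "random-monomorphic":
        pop_arr = np.full(Z, rng.integers(n_set), dtype=np.int64)
    else:
        pop_arr = rng.integers(n_set, size=Z)
    counts: dict[int, int] = {}
    for s in pop_arr:
        counts[int(s)] = counts.get(int(s), 0) + 1

    n_events, burn_in, n_blocks = config.n_events, config.burn_in, config.n_blocks
    block_len = (n_events - burn_in) / n_blocks
    block_acc = np.zeros((n_blocks, n_set))
    last_flush = burn_in

    def flush(upto: int) -> None:
        nonlocal last_flush
        if upto <= last_flush:
            return
        cur = last_flush
        while cur < upto:
            bidx = min(int((cur - burn_in) / block_len), n_blocks - 1)
            block_end = burn_in + (bidx + 1) * block_len
            take = min(upto, block_end) - cur
            if take <= 0:  # guard against float rounding at block edges
                take = upto - cur
            w = float(take)
            for s, c in counts.items():
                block_acc[bidx, s] += c * w
            cur += take
        last_flush = upto

    n_mutations = 0
    n_switches = 0
    ev = 0
    while ev < n_events:
        m = min(_BLOCK, n_events - ev)
        focal_blk = rng.integers(Z, size=m)
        model_blk = rng.integers(Z - 1, size=m)
        u_mut = rng.random(m)
        u_acc = rng.random(m)
        for t in range(m):
            e = ev + t
            focal = int(focal_blk[t])
            s_f = int(pop_arr[focal])
            if u_mut[t] < mu:
                s_new = int(rng.integers(n_set))
                if s_new != s_f:
                    if e + 1 > burn_in:
                        flush(e + 1)
                    _apply(pop_arr, counts, focal, s_f, s_new)
                    n_mutations += 1
                continue
            model = int(model_blk[t])
            if model >= focal:
                model += 1  # uniform over the other Z-1 individuals
            s_m = int(pop_arr[model])
            if s_m == s_f:
                continue
            if sampled:
                f_f = _sampled_fitness(pop_arr, focal, tables, rng, config)
                f_m = _sampled_fitness(pop_arr, model, tables, rng, config)
            elif len(counts) == 2:
                i, j = counts
                k_i = counts[i]
                f_i, f_j = tables.two_type(i, j, k_i)
                f_f, f_m = (f_i, f_j) if s_f == i else (f_j, f_i)
            else:
                f_f = tables.exact_multi(s_f, counts)
                f_m = tables.exact_multi(s_m, counts)
            x = -beta * (f_m - f_f)
            p = np.exp(-x) / (1.0 + np.exp(-x)) if x >= 0 else 1.0 / (1.0 + np.exp(x))
            if u_acc[t] < p:
                if e + 1 > burn_in:
                    flush(e + 1)
                _apply(pop_arr, counts, focal, s_f, s_m)
                n_switches += 1
        ev += m
    flush(n_events)

    weights = block_acc.sum(axis=0)
    strategy_freq = weights / weights.sum()
    block_freq = block_acc / block_acc.sum(axis=1, keepdims=True)
    bits = _set_bits(strategy_set)
    bit_freq = strategy_freq @ bits
    if all(isinstance(s, Strategy) for s in strategy_set):
        bmat = np.array([s.bits for s in strategy_set], dtype=np.int8)
        _, coop_rates = _monomorphic_arrays(bmat, gp)
    else:
        from .sml import monomorphic_cooperation_rate

        coop_rates = np.array(
            [monomorphic_cooperation_rate(s, gp) for s in strategy_set]
        )
    return ABMResult(
        config=config,
        strategy_freq=strategy_freq,
        bit_freq=bit_freq,
        block_strategy_freq=block_freq,
        cooperation=float(strategy_freq @ coop_rates),
        n_mutations=n_mutations,
        n_switches=n_switches,
    )


def _apply(
    pop_arr: np.ndarray, counts: dict[int, int], focal: int, s_old: int, s_new: int
) -> None:
    pop_arr[focal] = s_new
    counts[s_old] -= 1
    if counts[s_old] == 0:
        del counts[s_old]
    counts[s_new] = counts.get(s_new, 0) + 1


def _sampled_fitness(
    pop_arr: np.ndarray,
    member: int,
    tables: _FitnessTables,
    rng: np.random.Generator,
    config: ABMConfig,
) -> float:
    """Monte Carlo fitness: one stochastic playout per sampled group.

    Groups of N-1 co-players are drawn without replacement from the other
    Z-1 individuals; each group plays one full repeated game (geometric
    rounds, execution errors) and the focal's per-round-average payoffs
    are averaged over groups.
    """
    gp = config.game_params
    Z, N, w = config.pop.Z, gp.N, gp.w
    F, c = gp.F, gp.c
    others = np.delete(np.arange(Z), member)
    s_focal = int(pop_arr[member])
    focal_prof = tables.profiles[s_focal]
    total = 0.0
    for _ in range(config.n_sample_groups):
        mates = rng.choice(others, size=N - 1, replace=False)
        profs = [focal_prof] + [tables.profiles[int(pop_arr[m])] for m in mates]
        rounds = int(rng.geometric(1.0 - w)) if w > 0 else 1
        payoff = 0.0
        acts = np.array([rng.random() < p.p_initial for p in profs])
        for t in range(rounds):
            if t > 0:
                q_prev = k
                acts = np.array(
                    [rng.random() < p.p_after[q_prev] for p in profs]
                )
            k = int(acts.sum())
            payoff += F * c * k / N - c * float(acts[0])
        total += payoff / rounds
    return total / config.n_sample_groups


@dataclass(frozen=True)
class ComparisonReport:
    """Divergence between an ABM run and an SML result."""

    bit_abs_diff: np.ndarray
    bit_se: np.ndarray
    max_bit_diff: float
    tv_distance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"max per-bit |diff| = {self.max_bit_diff:.4f}, "
            f"TV(strategy freq) = {self.tv_distance:.4f}"
        )


def compare_abm_sml(abm: ABMResult, sml: SMLResult) -> ComparisonReport:
    """Per-bit absolute differences and total-variation distance.

    Requires matching game/population parameters apart from the mutation
    rate (the SML is the mu -> 0 limit) and identical strategy sets.
    """
    if abm.config.game_params != sml.game_params:
        raise ValueError("game parameters differ between ABM and SML results")
    if (abm.config.pop.Z, abm.config.pop.beta) != (sml.pop.Z, sml.pop.beta):
        raise ValueError("population parameters (Z, beta) differ")
    abm_set = _resolved_set(abm.config)
    if len(abm_set) != len(sml.strategy_set):
        raise ValueError("strategy sets differ in size")
    for a, b in zip(abm_set, sml.strategy_set):
        ida = a.id if isinstance(a, Strategy) else None
        idb = b.id if isinstance(b, Strategy) else None
        if ida != idb:
            raise ValueError("strategy sets differ")
    diff = np.abs(abm.bit_freq - sml.bit_dist)
    tv = 0.5 * float(np.abs(abm.strategy_freq - sml.tau).sum())
    return ComparisonReport(
        bit_abs_diff=diff,
        bit_se=abm.bit_se,
        max_bit_diff=float(diff.max()),
        tv_distance=tv,
    )
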