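"""Finite-population pairwise-comparison (Fermi) dynamics for two strategies.

A well-mixed population of Z individuals holds k players of strategy A and
Z-k of B.  Groups of N are sampled without replacement, so composition-
dependent fitness is a hypergeometric average of the exact group payoffs.
Imitation follows the Fermi rule p = [1 + exp(-beta (f_B - f_A))]^-1 with
selection intensity beta; the gradient of selection G(k) = T+(k) - T-(k)
gives the most likely direction of change, and fixation probabilities of
single mutants follow the standard birth-death ratio formula, evaluated in
log space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .game import GameParams, GroupComposition, expected_group_payoff
from .strategies import BehaviorProfile, Strategy

__all__ = [
    "PopulationParams",
    "PairPayoffTable",
    "GradientProfile",
    "fitness_pair",
    "imitation_probability",
    "transition_rates",
    "gradient_of_selection",
    "fixation_probability",
    "fixation_from_fitness",
]

Profile = Union[Strategy, BehaviorProfile]


@dataclass(frozen=True)
class PopulationParams:
    """Population size Z, selection intensity beta, mutation rate mu (ABM)."""

    Z: int
    beta: float = 1.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.Z < 2:
            raise ValueError(f"Z must be >= 2, got {self.Z}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")


@dataclass(frozen=True)
class PairPayoffTable:
    """Exact group payoffs for an ordered profile pair at every composition.

    ``pi_a[n_a]`` is the per-round expected payoff of one A-player in a
    group with n_a A-players (NaN at n_a = 0); ``pi_b[n_a]`` the analogue
    for a B-player (NaN at n_a = N); ``coop_rate[n_a]`` the expected
    fraction of cooperative acts.  This table is the bridge between the
    game engine and the population dynamics.
    """

    profile_a: Profile
    profile_b: Profile
    params: GameParams
    pi_a: np.ndarray = field(repr=False)
    pi_b: np.ndarray = field(repr=False)
    coop_rate: np.ndarray = field(repr=False)

    @classmethod
    def build(
        cls, profile_a: Profile, profile_b: Profile, params: GameParams
    ) -> "PairPayoffTable":
        N = params.N
        pi_a = np.empty(N + 1)
        pi_b = np.empty(N + 1)
        coop = np.empty(N + 1)
        for n_a in range(N + 1):
            comp = GroupComposition(N=N, n_a=n_a)
            pi_a[n_a], pi_b[n_a], coop[n_a] = expected_group_payoff(
                profile_a, profile_b, comp, params
            )
        return cls(profile_a, profile_b, params, pi_a, pi_b, coop)

    def swapped(self) -> "PairPayoffTable":
        """The same table with the A/B labels exchanged."""
        return PairPayoffTable(
            self.profile_b,
            self.profile_a,
            self.params,
            self.pi_b[::-1].copy(),
            self.pi_a[::-1].copy(),
            self.coop_rate[::-1].copy(),
        )


def group_sampling_weights(Z: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric weights for the N-1 co-players of a focal individual.

    Returns (H_a, H_b), each of shape (Z-1, N): row k-1 weights the number
    j = 0..N-1 of A-players among the focal's N-1 co-players when the
    population holds k A-players.  H_a excludes the focal A-player from the
    pool (k-1 A's among Z-1 others); H_b uses all k A's among Z-1 others.
    """
    ks = np.arange(1, Z)
    js = np.arange(N)
    H_a = hypergeom.pmf(js[None, :], Z - 1, (ks - 1)[:, None], N - 1)
    H_b = hypergeom.pmf(js[None, :], Z - 1, ks[:, None], N - 1)
    return H_a, H_b


def fitness_pair(k: int, table: PairPayoffTable, Z: int) -> tuple[float, float]:
    """Fitness (f_A, f_B) when k of Z use A, averaging over random groups.

    f_A(k) = sum_j H(j; Z-1, k-1, N-1) pi_A(n_a = j+1): the focal A-player
    plus j A's among its N-1 co-players drawn without replacement from the
    other Z-1 individuals.  f_B analogous with k A's in the pool.
    Monomorphic edges (k = 0 or Z) return the monomorphic group payoff for
    the resident and NaN for the absent type.
    """
    N = table.params.N
    if not 0 <= k <= Z:
        raise ValueError(f"k must be in [0, {Z}], got {k}")
    if k == Z:
        return float(table.pi_a[N]), float("nan")
    if k == 0:
        return float("nan"), float(table.pi_b[0])
    js = np.arange(N)
    w_a = hypergeom.pmf(js, Z - 1, k - 1, N - 1)
    w_b = hypergeom.pmf(js, Z - 1, k, N - 1)
    f_a = float(w_a @ table.pi_a[1:])
    f_b = float(w_b @ table.pi_b[:N])
    return f_a, f_b


def fitness_profile(table: PairPayoffTable, Z: int) -> tuple[np.ndarray, np.ndarray]:
    """(f_A(k), f_B(k)) for k = 1..Z-1 as length Z-1 arrays."""
    H_a, H_b = group_sampling_weights(Z, table.params.N)
    return H_a @ table.pi_a[1:], H_b @ table.pi_b[: table.params.N]


def imitation_probability(f_a: float, f_b: float, beta: float) -> float:
    """Fermi probability that the focal A-player imitates model B."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    # expit-style guard against overflow for large |beta * df|
    x = -beta * (f_b - f_a)
    if x >= 0:
        return float(np.exp(-x) / (1.0 + np.exp(-x)))
    return float(1.0 / (1.0 + np.exp(x)))


def transition_rates(
    k: int, table: PairPayoffTable, pop: PopulationParams
) -> tuple[float, float]:
    """(T+, T-): probabilities that the count of A-players rises or falls.

    A focal individual is drawn uniformly from Z, a model uniformly from
    the remaining Z-1, and the focal imitates with the Fermi probability.
    Monomorphic states are absorbing (rates 0) absent mutation.
    """
    Z = pop.Z
    if not 0 <= k <= Z:
        raise ValueError(f"k must be in [0, {Z}], got {k}")
    if k == 0 or k == Z:
        return 0.0, 0.0
    f_a, f_b = fitness_pair(k, table, Z)
    frac = k * (Z - k) / (Z * (Z - 1))
    t_plus = frac * imitation_probability(f_b, f_a, pop.beta)  # B imitates A
    t_minus = frac * imitation_probability(f_a, f_b, pop.beta)  # A imitates B
    return t_plus, t_minus


@dataclass(frozen=True)
class GradientRoot:
    """Interior sign change of G bracketed by (k_lo, k_hi)."""

    k_lo: int
    k_hi: int
    k_interp: float
    stable: bool  # True when G crosses + -> - (attractor)


@dataclass(frozen=True)
class GradientProfile:
    """G(k) = T+(k) - T-(k) over k = 0..Z with classified interior roots."""

    k: np.ndarray
    t_plus: np.ndarray
    t_minus: np.ndarray
    roots: tuple[GradientRoot, ...]

    @property
    def G(self) -> np.ndarray:
        return self.t_plus - self.t_minus


def gradient_of_selection(
    table: PairPayoffTable, pop: PopulationParams
) -> GradientProfile:
    """Gradient of selection for A vs B with root bracketing/classification."""
    Z = pop.Z
    t_plus = np.zeros(Z + 1)
    t_minus = np.zeros(Z + 1)
    f_a, f_b = fitness_profile(table, Z)
    ks = np.arange(1, Z)
    frac = ks * (Z - ks) / (Z * (Z - 1))
    with np.errstate(over="ignore"):
        t_plus[1:Z] = frac / (1.0 + np.exp(-pop.beta * (f_a - f_b)))
        t_minus[1:Z] = frac / (1.0 + np.exp(pop.beta * (f_a - f_b)))
    G = t_plus - t_minus
    roots: list[GradientRoot] = []
    for k in range(1, Z - 1):
        g0, g1 = G[k], G[k + 1]
        if g0 * g1 < 0:  # strict sign change between adjacent counts
            x = k + g0 / (g0 - g1)
            roots.append(GradientRoot(k, k + 1, float(x), stable=g0 > 0))
    return GradientProfile(
        k=np.arange(Z + 1), t_plus=t_plus, t_minus=t_minus, roots=tuple(roots)
    )


def fixation_from_fitness(
    f_mut: np.ndarray, f_res: np.ndarray, beta: float
) -> float:
    """Fixation probability from mutant/resident fitness at counts 1..Z-1.

    rho = [sum_{i=0}^{Z-1} prod_{j<=i} T-(j)/T+(j)]^-1 with the ratio equal
    to exp(-beta (f_mut(j) - f_res(j))); the sum is a logsumexp over
    cumulative log-ratios, immune to overflow at strong selection.
    """
    log_ratio = -beta * (np.asarray(f_mut) - np.asarray(f_res))
    cum = np.concatenate(([0.0], np.cumsum(log_ratio)))
    return float(np.exp(-logsumexp(cum)))


def fixation_probability(
    mutant: Profile,
    resident: Profile,
    game_params: GameParams,
    pop: PopulationParams,
    table: PairPayoffTable | None = None,
) -> float:
    """Probability that a single mutant takes over the resident population.

    ``table`` may supply a precomputed payoff table with A = mutant,
    B = resident; otherwise it is built from the exact game engine.
    At beta = 0 this is the neutral 1/Z for any pair.
    """
    if table is None:
        table = PairPayoffTable.build(mutant, resident, game_params)
    f_mut, f_res = fitness_profile(table, pop.Z)
    return fixation_from_fitness(f_mut, f_res, pop.beta)
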