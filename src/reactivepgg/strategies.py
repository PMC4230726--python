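"""Reactive strategies for the repeated N-person public goods game.

A reactive strategy for a group of size ``N`` is an ``N+2``-bit string
``b^-1 b^0 b^1 ... b^N``.  The first bit ``b^-1`` fixes the move in the
opening round; bit ``b^q`` (``0 <= q <= N``) fixes the move after observing
``q`` cooperators in the previous round.  Bit value 1 is a cooperative act,
0 a defective one, so the full strategy space for group size ``N`` has
``2**(N+2)`` elements.

Integer ids encode the bit string with ``b^-1`` as the most significant bit
and ``b^N`` as the least significant, so ids are stable across runs and
output files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "Strategy",
    "BehaviorProfile",
    "encode_strategy",
    "decode_strategy",
    "named_strategy",
    "enumerate_strategies",
    "bits_matrix",
    "InvalidStrategyError",
]


class InvalidStrategyError(ValueError):
    """Raised for malformed bit strings, out-of-range ids or bad names."""


@dataclass(frozen=True)
class Strategy:
    """A pure reactive strategy: an (N+2)-bit rule plus its integer id."""

    N: int
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.N < 2:
            raise InvalidStrategyError(f"group size must be >= 2, got {self.N}")
        if len(self.bits) != self.N + 2:
            raise InvalidStrategyError(
                f"expected {self.N + 2} bits for N={self.N}, got {len(self.bits)}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise InvalidStrategyError(f"bits must be 0/1, got {self.bits}")

    @property
    def id(self) -> int:
        return encode_strategy(self.bits)

    @property
    def first_move(self) -> int:
        """The opening-round bit b^-1."""
        return self.bits[0]

    def response(self, q: int) -> int:
        """Intended act after observing q cooperators in the previous round."""
        if not 0 <= q <= self.N:
            raise ValueError(f"q must be in [0, {self.N}], got {q}")
        return self.bits[q + 1]

    def to_string(self) -> str:
        """Render as ``"b-1|b0...bN"``, e.g. ``"0|100001"`` for AoN at N=5."""
        return f"{self.bits[0]}|{''.join(map(str, self.bits[1:]))}"

    @classmethod
    def from_string(cls, s: str) -> "Strategy":
        m = re.fullmatch(r"([01])\|([01]+)", s.strip())
        if m is None:
            raise InvalidStrategyError(f"cannot parse strategy string {s!r}")
        bits = (int(m.group(1)),) + tuple(int(ch) for ch in m.group(2))
        return cls(N=len(bits) - 2, bits=bits)

    def profile(self, eps: float = 0.0) -> "BehaviorProfile":
        """Behavior profile with execution-error rate ``eps`` applied.

        Each intended act is flipped with probability eps, so a bit b
        yields cooperation probability ``b(1-eps) + (1-b)eps``.
        """
        b = np.asarray(self.bits, dtype=float)
        return BehaviorProfile(N=self.N, coop_prob=b * (1.0 - eps) + (1.0 - b) * eps)


@dataclass(frozen=True)
class BehaviorProfile:
    """Probabilistic reactive rule: P(cooperate) for the opening round and
    for each observed cooperator count q = 0..N.

    Generalizes pure strategies (entries in {eps, 1-eps}) and houses the
    random strategist, whose entries are all 0.5.
    """

    N: int
    coop_prob: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.coop_prob, dtype=float)
        if p.shape != (self.N + 2,):
            raise InvalidStrategyError(
                f"coop_prob must have length {self.N + 2}, got shape {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise InvalidStrategyError("cooperation probabilities must lie in [0, 1]")
        object.__setattr__(self, "coop_prob", p)

    @property
    def p_initial(self) -> float:
        return float(self.coop_prob[0])

    @property
    def p_after(self) -> np.ndarray:
        """Cooperation probabilities conditioned on q = 0..N, length N+1."""
        return self.coop_prob[1:]


def encode_strategy(bits: Sequence[int]) -> int:
    """Pack a bit sequence (b^-1 first, b^N last) into an integer id."""
    bits = tuple(bits)
    if len(bits) < 4:
        raise InvalidStrategyError(f"need at least 4 bits (N >= 2), got {len(bits)}")
    if any(b not in (0, 1) for b in bits):
        raise InvalidStrategyError(f"bits must be 0/1, got {bits}")
    out = 0
    for b in bits:
        out = (out << 1) | b
    return out


def decode_strategy(strategy_id: int, N: int) -> Strategy:
    """Inverse of :func:`encode_strategy` for group size ``N``."""
    n_bits = N + 2
    if not 0 <= strategy_id < (1 << n_bits):
        raise InvalidStrategyError(
            f"id {strategy_id} out of range [0, {1 << n_bits}) for N={N}"
        )
    bits = tuple((strategy_id >> (n_bits - 1 - i)) & 1 for i in range(n_bits))
    return Strategy(N=N, bits=bits)


def enumerate_strategies(N: int) -> list[Strategy]:
    """All ``2**(N+2)`` reactive strategies for group size ``N``, by id."""
    if N < 2:
        raise InvalidStrategyError(f"group size must be >= 2, got {N}")
    return [decode_strategy(i, N) for i in range(1 << (N + 2))]


def bits_matrix(N: int, ids: Iterable[int] | None = None) -> np.ndarray:
    """Bit matrix of shape (n_strategies, N+2) with columns b^-1, b^0..b^N.

    With ``ids=None`` covers the full space in id order.
    """
    n_bits = N + 2
    if ids is None:
        id_arr = np.arange(1 << n_bits, dtype=np.int64)
    else:
        id_arr = np.asarray(list(ids), dtype=np.int64)
        if id_arr.size and (id_arr.min() < 0 or id_arr.max() >= (1 << n_bits)):
            raise InvalidStrategyError("strategy id out of range")
    shifts = np.arange(n_bits - 1, -1, -1)
    return ((id_arr[:, None] >> shifts[None, :]) & 1).astype(np.int8)


_DEFAULT_FIRST_MOVE = {"AoN": 0, "AllD": 0, "AllC": 1, "GR": 1}


def named_strategy(
    name: str,
    N: int,
    first_move: Union[int, str] = "default",
) -> Union[Strategy, BehaviorProfile]:
    """Construct a canonical strategy by name.

    Names: ``AoN`` (all-or-none: cooperate only after unanimity, b^0=b^N=1,
    interior bits 0), ``AllD``, ``AllC``, ``GR_M`` (generalized reciprocator:
    cooperate iff at least M cooperated), ``RS`` (random strategist — returned
    as a :class:`BehaviorProfile` with probability 1/2 everywhere).

    ``first_move`` overrides b^-1; defaults are 1 for AllC and GR_M, 0 for
    AllD and AoN (results are insensitive to the AoN opening bit).
    """
    key = name.strip()
    m = re.fullmatch(r"GR_(\d+)", key)
    if m is not None:
        M = int(m.group(1))
        if not 0 <= M <= N:
            raise InvalidStrategyError(f"GR threshold M={M} out of range [0, {N}]")
        resp = tuple(1 if q >= M else 0 for q in range(N + 1))
        fm = _DEFAULT_FIRST_MOVE["GR"] if first_move == "default" else int(first_move)
        return Strategy(N=N, bits=(fm,) + resp)
    if key == "RS":
        if first_move != "default":
            raise InvalidStrategyError("RS has no configurable first move")
        return BehaviorProfile(N=N, coop_prob=np.full(N + 2, 0.5))
    if key == "AoN":
        resp = tuple(1 if q in (0, N) else 0 for q in range(N + 1))
    elif key == "AllD":
        resp = (0,) * (N + 1)
    elif key == "AllC":
        resp = (1,) * (N + 1)
    else:
        raise InvalidStrategyError(f"unknown strategy name {name!r}")
    fm = _DEFAULT_FIRST_MOVE[key] if first_move == "default" else int(first_move)
    if fm not in (0, 1):
        raise InvalidStrategyError(f"first_move must be 0 or 1, got {first_move!r}")
    return Strategy(N=N, bits=(fm,) + resp)
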