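"""Sequential entropy of a monomer/oligomer mixture and its reciprocal.

The walk through a mixture of ``N`` units encounters ``W = N/(M + L/2)``
chains; each encounter contributes three independent choices — which
free monomers were crossed (mixing), where the chain was contacted
(contact) and how its sequence reads (sequence).  The total

    S_r / k = W * [ M * Σ_i r_i ln(1/r_i)
                    + Σ_j a_j ln(1/a_j)
                    + (L/2) * Σ_k p_k ln(1/p_k) ]

is reported in units of k and in J/K; its reciprocal (in K/J) is the
system's order parameter.  Four limiting closed forms (pure monomer,
crystals, random chains, defined chains) are exposed separately and are
exact algebraic reductions of the general expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .system_model import BOLTZMANN, ParameterError, SystemState, make_uniform_state

__all__ = [
    "EntropyBreakdown",
    "entropy_general",
    "entropy_two_level",
    "entropy_uniform",
    "limiting_case_entropy",
    "order_parameter",
    "living_dead_gap",
    "InfiniteOrderError",
    "LIMITING_CASES",
]

LIMITING_CASES = ("pure_monomer", "crystals", "random_chains", "defined_chains")


class InfiniteOrderError(ZeroDivisionError):
    """Raised when order 1/S_r is requested for a zero-entropy system."""


def _xlogx(values) -> float:
    """Σ v ln(1/v) with the continuous extension 0·ln(1/0) = 0."""
    total = 0.0
    for v in values:
        if v < 0:
            raise ParameterError("profile", f"negative weight {v}")
        if v > 0:
            total -= v * math.log(v)
    return total


@dataclass(frozen=True)
class EntropyBreakdown:
    """Additive decomposition of the sequential entropy.

    All three terms are in units of k (dimensionless); ``S_r_k`` is
    their sum, ``S_r_JK`` the same in J/K, and ``order_KJ`` the
    reciprocal of ``S_r_JK`` (``inf`` for a zero-entropy system).
    """

    term_mixing: float
    term_contact: float
    term_sequence: float
    W: float

    @property
    def S_r_k(self) -> float:
        return self.term_mixing + self.term_contact + self.term_sequence

    @property
    def S_r_JK(self) -> float:
        return self.S_r_k * BOLTZMANN

    @property
    def order_KJ(self) -> float:
        s = self.S_r_JK
        return math.inf if s == 0.0 else 1.0 / s

    def to_dict(self) -> dict:
        return {
            "term_mixing": self.term_mixing,
            "term_contact": self.term_contact,
            "term_sequence": self.term_sequence,
            "W": self.W,
            "S_r_k": self.S_r_k,
            "S_r_JK": self.S_r_JK,
            "order_KJ": self.order_KJ,
        }


def entropy_general(state: SystemState) -> EntropyBreakdown:
    """Three-term sequential entropy with explicit r, a and p_k profiles.

    Requires all three profiles on ``state`` (``a`` may be omitted only
    for integer-free uniform handling via :func:`entropy_two_level` /
    :func:`entropy_uniform`).  Zero profile entries contribute nothing
    (0·ln(1/0) = 0).
    """
    if state.pk is None:
        raise ParameterError(
            "pk", "explicit predictability profile required; use entropy_two_level/entropy_uniform"
        )
    W = state.W
    mixing = state.M * W * _xlogx(state.r)
    contact = W * (_xlogx(state.a) if state.a is not None else math.log(state.L))
    sequence = (state.L / 2.0) * W * _xlogx(state.pk)
    return EntropyBreakdown(mixing, contact, sequence, W)


def entropy_two_level(state: SystemState, p: float | None = None) -> EntropyBreakdown:
    """Sequential entropy for a defined/random two-level chain population.

    A fraction ``p`` of the chains is fully random (p_k = 1/n each) and
    ``1 - p`` fully defined (p_k = [1, 0, ...]); the sequence term then
    collapses to ``k p (L/2) W ln n``.  ``p`` defaults to ``state.p``.
    """
    if p is None:
        p = state.p
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p", f"must lie in [0, 1], got {p}")
    W = state.W
    mixing = state.M * W * _xlogx(state.r)
    contact = W * (_xlogx(state.a) if state.a is not None else math.log(state.L))
    sequence = p * (state.L / 2.0) * W * math.log(state.n)
    return EntropyBreakdown(mixing, contact, sequence, W)


def entropy_uniform(n: int, N: float, L: float, M: float, p: float) -> EntropyBreakdown:
    """Sequential entropy for uniform composition and accessibility.

        S_r / k = W * [ M ln n + ln L + p (L/2) ln n ],   W = N/(M + L/2)

    This is the workhorse used by the sweeps and the evolution runs.
    """
    state = make_uniform_state(n, N, L, M, p)
    W = state.W
    ln_n = math.log(n)
    return EntropyBreakdown(M * W * ln_n, W * math.log(L), p * (L / 2.0) * W * ln_n, W)


def limiting_case_entropy(case: str, n: int, N: float, L: float = 1.0) -> float:
    """Closed-form sequential entropy (units of k) for a canonical case.

    ``pure_monomer``  → N ln n
    ``crystals``      → (2N/L) ln L      (single-type interior, n irrelevant)
    ``random_chains`` → (2N/L) ln L + N ln n
    ``defined_chains``→ (2N/L) ln L
    """
    if n < 1:
        raise ParameterError("n", f"must be >= 1, got {n}")
    if N <= 0:
        raise ParameterError("N", f"must be > 0, got {N}")
    if case == "pure_monomer":
        return N * math.log(n)
    if case not in LIMITING_CASES:
        raise ParameterError("case", f"unknown case {case!r}; expected one of {LIMITING_CASES}")
    if L < 1:
        raise ParameterError("L", f"must be >= 1 for case {case!r}, got {L}")
    contact = (2.0 * N / L) * math.log(L)
    if case == "random_chains":
        return contact + N * math.log(n)
    return contact  # crystals and defined_chains share the same form


def order_parameter(S_r_JK: float) -> float:
    """Order of the system: reciprocal sequential entropy, K/J."""
    if S_r_JK < 0:
        raise ParameterError("S_r_JK", f"must be >= 0, got {S_r_JK}")
    if S_r_JK == 0.0:
        raise InfiniteOrderError(
            "zero sequential entropy: single-microstate system has unbounded order"
        )
    return 1.0 / S_r_JK


def living_dead_gap(n: int, N: float) -> float:
    """Entropy gap (units of k) between fully random and fully defined
    chain populations of equal length: N ln n."""
    if n < 1:
        raise ParameterError("n", f"must be >= 1, got {n}")
    if N <= 0:
        raise ParameterError("N", f"must be > 0, got {N}")
    return N * math.log(n)
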