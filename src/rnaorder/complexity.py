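"""Minimal-description-length complexity of a monomer/chain mixture.

Two encoding strategies bound the size (in bits) of the smallest
program reproducing the walk statistics of the system:

* strategy (a): tabulate all ``n**L`` possible chain sequences and store
  one occurrence counter per permutation — ``c1``;
* strategy (b): list every chain sequence explicitly — ``c2``.

The complexity is ``c = min(c1, c2)``.  For a mixed population where a
fraction ``p`` of the ``N/(L+M)`` chains met per walk is random,

    c1 ≈ L log2 n + n**L * log2(p N / (L + M))
    c2 ≈ L log2 n + L * (p N / (L + M)) * log2 n

``n**L`` overflows double precision quickly, so every estimate is also
carried as a decimal logarithm and strategy comparison happens in the
log domain whenever either side is not representable.  A census of at
most one random chain costs nothing: ``log2`` of a count <= 1 is
clamped to zero, so the estimates degrade gracefully to the
defined-chain cost ``L log2 n`` as p -> 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .system_model import ParameterError

__all__ = [
    "ComplexityEstimate",
    "defined_chain_complexity",
    "c1_random",
    "c2_explicit",
    "c1_mixed",
    "c2_mixed",
    "system_complexity",
    "DegenerateCensusWarning",
]

_LOG10_MAX = 308.0  # beyond this, carry bits only as log10


class DegenerateCensusWarning(UserWarning):
    """The chain census is empty or has at most one entry; its encoding
    cost is clamped to zero."""


def _validate(n: int, L: float, N: float | None = None, p: float | None = None,
              M: float | None = None) -> None:
    if n < 1:
        raise ParameterError("n", f"must be >= 1, got {n}")
    if L < 1:
        raise ParameterError("L", f"must be >= 1, got {L}")
    if N is not None and N <= 0:
        raise ParameterError("N", f"must be > 0, got {N}")
    if p is not None and not (0.0 <= p <= 1.0):
        raise ParameterError("p", f"must lie in [0, 1], got {p}")
    if M is not None and M < 0:
        raise ParameterError("M", f"must be >= 0, got {M}")


def _census_term(n: int, L: float, count: float) -> tuple[float, float]:
    """(value, log10) of n**L * log2(count), clamped to 0 for count <= 1."""
    if count <= 1.0 or n == 1 and count <= 1.0:
        return 0.0, -math.inf
    log2_count = math.log2(count)
    log10 = L * math.log10(n) + math.log10(log2_count)
    value = math.inf if log10 > _LOG10_MAX else 10.0 ** log10
    # recompute directly when representable: cheaper rounding than 10**x
    if value < math.inf:
        direct = n ** L * log2_count if isinstance(L, int) else math.exp(L * math.log(n)) * log2_count
        if math.isfinite(direct):
            value = direct
    return value, log10


def _as_log10(x: float) -> float:
    return math.log10(x) if x > 0 else -math.inf


def _log10_sum(*log10s: float) -> float:
    finite = [x for x in log10s if x > -math.inf]
    if not finite:
        return -math.inf
    m = max(finite)
    return m + math.log10(sum(10.0 ** (x - m) for x in finite))


def defined_chain_complexity(L: float, n: int) -> float:
    """Description length (bits) of one fully defined chain: L log2 n."""
    _validate(n, L)
    return L * math.log2(n) if n > 1 else 0.0


def c1_random(n: int, L: float, N: float) -> float:
    """Strategy-(a) cost for a fully random population: n**L log2(N/L).

    A census with at most one chain (N/L <= 1) is freely compressible;
    the cost is then 0 and a :class:`DegenerateCensusWarning` is issued.
    May return ``inf`` when the value exceeds double precision; use
    :func:`system_complexity` for an overflow-safe log-scale estimate.
    """
    _validate(n, L, N=N)
    if N / L <= 1.0:
        warnings.warn("chain census N/L <= 1: cost clamped to 0", DegenerateCensusWarning,
                      stacklevel=2)
        return 0.0
    return _census_term(n, L, N / L)[0]


def c2_explicit(N: float, n: int) -> float:
    """Strategy-(b) cost for a fully random population: N log2 n."""
    _validate(n, 1.0, N=N)
    return N * math.log2(n) if n > 1 else 0.0


def c1_mixed(n: int, L: float, p: float, N: float, M: float) -> float:
    """Strategy-(a) cost for a mixed defined/random population.

    ``L log2 n`` for the shared defined sequence plus a permutation
    census over the ``p N / (L + M)`` random chains met per walk.  The
    census term is clamped to 0 when ``p = 0`` or the count is <= 1, so
    the result reduces exactly to the defined-chain cost.
    """
    _validate(n, L, N=N, p=p, M=M)
    defined = L * math.log2(n) if n > 1 else 0.0
    census, _ = _census_term(n, L, p * N / (L + M))
    return defined + census


def c2_mixed(n: int, L: float, p: float, N: float, M: float) -> float:
    """Strategy-(b) cost for a mixed population:
    ``L log2 n + L (p N / (L + M)) log2 n``."""
    _validate(n, L, N=N, p=p, M=M)
    if n == 1:
        return 0.0
    return L * math.log2(n) + L * (p * N / (L + M)) * math.log2(n)


@dataclass(frozen=True)
class ComplexityEstimate:
    """Both strategy costs and their minimum, with log-scale backups.

    ``c1``/``c2``/``c`` are bit counts (``inf`` when not representable
    in double precision); the ``log10_*`` fields are always meaningful
    for positive costs (``-inf`` encodes an exact zero).
    """

    c1: float
    c2: float
    log10_c1: float
    log10_c2: float
    strategy: str  # 'a' or 'b'

    @property
    def c(self) -> float:
        return self.c1 if self.strategy == "a" else self.c2

    @property
    def log10_c(self) -> float:
        return self.log10_c1 if self.strategy == "a" else self.log10_c2

    def to_dict(self) -> dict:
        return {
            "c1_bits": self.c1,
            "c2_bits": self.c2,
            "c_bits": self.c,
            "log10_c": self.log10_c,
            "strategy": self.strategy,
        }


def system_complexity(n: int, L: float, p: float, N: float, M: float) -> ComplexityEstimate:
    """Overflow-safe mixed-population complexity: both strategies and
    their minimum.

    Strategies are compared via decimal logs whenever either bit count
    overflows double precision; ties resolve to strategy 'a' so output
    is deterministic.
    """
    _validate(n, L, N=N, p=p, M=M)
    defined_bits = L * math.log2(n) if n > 1 else 0.0
    log10_defined = _as_log10(defined_bits)

    census_val, census_log10 = _census_term(n, L, p * N / (L + M))
    log10_c1 = _log10_sum(log10_defined, census_log10)
    c1 = defined_bits + census_val  # inf-safe: inf + finite = inf

    if n > 1 and p * N > 0:
        listing_log10 = _log10_sum(
            math.log10(L) + math.log10(p * N / (L + M)) + math.log10(math.log2(n))
            if p > 0 else -math.inf,
        )
    else:
        listing_log10 = -math.inf
    listing_val = L * (p * N / (L + M)) * math.log2(n) if n > 1 else 0.0
    log10_c2 = _log10_sum(log10_defined, listing_log10)
    c2 = defined_bits + listing_val

    if math.isfinite(c1) and math.isfinite(c2):
        strategy = "a" if c1 <= c2 else "b"
    else:
        strategy = "a" if log10_c1 <= log10_c2 else "b"
    return ComplexityEstimate(c1, c2, log10_c1, log10_c2, strategy)
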