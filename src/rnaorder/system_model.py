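"""Parameter types describing a monomer/oligomer mixture.

The mean-field state of a mixture is a small tuple of parameters: the
alphabet size ``n`` with per-type contributions ``r_i``, the total unit
count ``N``, the mean chain length ``L``, the mean number of free
monomers ``M`` between chain encounters, the random-chain fraction
``p``, and two optional profiles — per-position predictability ``p_k``
and per-position chain accessibility ``a_j``.  No sequences or spatial
coordinates are stored; everything downstream is a closed-form function
of these numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter violates its domain constraint.

    Carries the offending field name in :attr:`field`.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def moles_to_units(moles: float) -> float:
    """Convert an amount in moles to an absolute unit count.

    Parameters
    ----------
    moles
        Amount of substance, must be >= 0.

    Returns
    -------
    float
        ``moles * 6.02214076e23``.
    """
    if moles < 0:
        raise ParameterError("moles", f"must be >= 0, got {moles}")
    return moles * AVOGADRO


def _check_profile(name: str, values: Sequence[float], *, non_increasing: bool = False) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ParameterError(name, "profile must be non-empty")
    for v in vals:
        if not (0.0 <= v <= 1.0) or math.isnan(v):
            raise ParameterError(name, f"entries must lie in [0, 1], got {v}")
    if abs(sum(vals) - 1.0) > _SUM_TOL * max(1.0, len(vals)):
        raise ParameterError(name, f"entries must sum to 1, got {sum(vals)!r}")
    if non_increasing:
        for a, b in zip(vals, vals[1:]):
            if b > a + _SUM_TOL:
                raise ParameterError(name, "entries must be non-increasing")
    return vals


@dataclass(frozen=True)
class Alphabet:
    """Monomer alphabet: ``n`` types with relative contributions ``r``.

    ``r`` defaults to the uniform composition ``1/n``.
    """

    n: int
    r: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not isinstance(self.n, int) or isinstance(self.n, bool):
            raise ParameterError("n", f"must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ParameterError("n", f"must be >= 1, got {self.n}")
        if self.r is None:
            object.__setattr__(self, "r", (1.0 / self.n,) * self.n)
        else:
            r = _check_profile("r", self.r)
            if len(r) != self.n:
                raise ParameterError("r", f"expected {self.n} entries, got {len(r)}")
            object.__setattr__(self, "r", r)

    @property
    def uniform(self) -> bool:
        return all(abs(ri - 1.0 / self.n) <= _SUM_TOL for ri in self.r)


@dataclass(frozen=True)
class SystemState:
    """One instant of a monomer/chain mixture, as a parameter tuple.

    Attributes
    ----------
    alphabet
        Monomer alphabet (``n`` and composition ``r``).
    N
        Total number of units (positive real; counts or moles×Avogadro).
    L
        Mean chain length in units (>= 1; fractional values allowed).
    M
        Mean number of free monomers between chain encounters (>= 0).
    p
        Fraction of chains carrying fully random sequences, in [0, 1].
    pk
        Optional predictability profile (n probabilities, non-increasing,
        summing to 1).  ``None`` means use the two-level ``p`` split.
    a
        Optional chain accessibility profile (``ceil(L)`` non-negative
        weights summing to 1).  ``None`` means uniform accessibility.
    """

    alphabet: Alphabet
    N: float
    L: float
    M: float
    p: float
    pk: tuple[float, ...] | None = None
    a: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (self.N > 0) or math.isinf(self.N) or math.isnan(self.N):
            raise ParameterError("N", f"must be > 0 and finite, got {self.N}")
        if not (self.L >= 1) or math.isinf(self.L):
            raise ParameterError("L", f"must be >= 1 and finite, got {self.L}")
        if not (self.M >= 0) or math.isinf(self.M):
            raise ParameterError("M", f"must be >= 0 and finite, got {self.M}")
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError("p", f"must lie in [0, 1], got {self.p}")
        if self.pk is not None:
            pk = _check_profile("pk", self.pk, non_increasing=True)
            if len(pk) != self.alphabet.n:
                raise ParameterError("pk", f"expected {self.alphabet.n} entries, got {len(pk)}")
            object.__setattr__(self, "pk", pk)
        if self.a is not None:
            a = _check_profile("a", self.a)
            if len(a) != math.ceil(self.L):
                raise ParameterError(
                    "a", f"expected ceil(L)={math.ceil(self.L)} entries, got {len(a)}"
                )
            object.__setattr__(self, "a", a)

    @property
    def n(self) -> int:
        return self.alphabet.n

    @property
    def r(self) -> tuple[float, ...]:
        return self.alphabet.r

    @property
    def W(self) -> float:
        """Number of chain encounters along one walk: N / (M + L/2)."""
        return self.N / (self.M + self.L / 2.0)

    @property
    def uniform(self) -> bool:
        """True when composition is uniform and no explicit profiles are set."""
        return self.alphabet.uniform and self.pk is None and self.a is None

    def with_(self, **kwargs) -> "SystemState":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        """Serializable representation (config-file round trip)."""
        d = {
            "n": self.n,
            "N_units": self.N,
            "L": self.L,
            "M": self.M,
            "p": self.p,
        }
        if not self.alphabet.uniform:
            d["r"] = list(self.r)
        if self.pk is not None:
            d["pk"] = list(self.pk)
        if self.a is not None:
            d["a"] = list(self.a)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemState":
        """Build a state from config-file keys (see :meth:`to_dict`)."""
        known = {"n", "r", "N_units", "N_moles", "L", "M", "p", "pk", "a"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown config key")
        if ("N_units" in d) == ("N_moles" in d):
            raise ParameterError("N_units", "exactly one of N_units / N_moles required")
        N = float(d["N_units"]) if "N_units" in d else moles_to_units(float(d["N_moles"]))
        alphabet = Alphabet(int(d["n"]), tuple(d["r"]) if d.get("r") is not None else None)
        return cls(
            alphabet=alphabet,
            N=N,
            L=float(d["L"]),
            M=float(d["M"]),
            p=float(d["p"]),
            pk=tuple(d["pk"]) if d.get("pk") is not None else None,
            a=tuple(d["a"]) if d.get("a") is not None else None,
        )


def make_uniform_state(n: int, N: float, L: float, M: float, p: float) -> SystemState:
    """Construct a state with uniform composition and accessibility.

    ``r_i = 1/n`` is implied and ``a_j = 1/L`` is left implicit (the
    uniform contact term reduces to ``ln L`` exactly, so no profile is
    stored).

    Raises
    ------
    ParameterError
        If any argument violates its domain constraint; the error names
        the offending field.
    """
    return SystemState(alphabet=Alphabet(n), N=float(N), L=float(L), M=float(M), p=float(p))
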