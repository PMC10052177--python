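"""Brute-force microstate oracles on tiny explicit unit arrangements.

Validates the closed-form entropy and complexity estimators on systems
small enough to enumerate.  A toy system is an ordered line of typed
units, some grouped into contiguous chains and some free; a
deterministic nearest-unvisited walk traverses it, and the variety of
walk readouts over an ensemble of arrangements stands in for the
statistical weight behind the sequential entropy.

Geometry is one-dimensional: "closest" means minimal absolute site
distance, ties break toward the lower site index.  Ensembles are built
by enumerating arrangements and walk starting points rather than by
time-stepping any dynamics.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.special import gammaln

__all__ = [
    "ChainSpec",
    "ToySystem",
    "WalkRecord",
    "build_toy_system",
    "toy_from_blocks",
    "sample_walk",
    "walk_ensemble_log_weight",
    "multinomial_mixing_entropy",
    "explicit_encoding_length",
    "canonical_ensembles",
]

FREE = -1  # chain_id marker for free monomers


@dataclass(frozen=True)
class ChainSpec:
    """Recipe for chain blocks in a toy system.

    ``kind`` is 'defined' (explicit ``sequence``, repeated exactly in
    every copy) or 'random' (``length`` units drawn uniformly per copy).
    """

    kind: str
    copies: int = 1
    sequence: tuple[int, ...] | None = None
    length: int | None = None

    def __post_init__(self):
        if self.kind not in ("defined", "random"):
            raise ValueError(f"kind must be 'defined' or 'random', got {self.kind!r}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.kind == "defined" and not self.sequence:
            raise ValueError("defined chain needs a sequence")
        if self.kind == "random" and not (self.length and self.length >= 1):
            raise ValueError("random chain needs a length >= 1")


@dataclass(frozen=True)
class ToySystem:
    """Explicit arrangement: per-site type labels and chain membership.

    Sites are consecutive integers from 0; chain members occupy
    consecutive sites; ``chain_ids[i] == FREE`` marks a free monomer.
    """

    n: int
    types: tuple[int, ...]
    chain_ids: tuple[int, ...]

    def __post_init__(self):
        if len(self.types) != len(self.chain_ids) or not self.types:
            raise ValueError("types and chain_ids must be equal-length and non-empty")
        if any(t < 0 or t >= self.n for t in self.types):
            raise ValueError(f"type labels must lie in [0, {self.n})")
        seen: dict[int, int] = {}
        for site, cid in enumerate(self.chain_ids):
            if cid == FREE:
                continue
            if cid in seen and site != seen[cid] + 1:
                raise ValueError(f"chain {cid} not contiguous at site {site}")
            seen[cid] = site

    @property
    def N(self) -> int:
        return len(self.types)

    def composition(self) -> tuple[int, ...]:
        counts = [0] * self.n
        for t in self.types:
            counts[t] += 1
        return tuple(counts)

    def chains(self) -> list[tuple[int, ...]]:
        """Chain sequences in order of appearance."""
        out: dict[int, list[int]] = {}
        for site, cid in enumerate(self.chain_ids):
            if cid != FREE:
                out.setdefault(cid, []).append(self.types[site])
        return [tuple(seq) for seq in out.values()]

    def chain_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(len(c) for c in self.chains()))


@dataclass(frozen=True)
class WalkRecord:
    """One deterministic walk: the visit order and its type readout."""

    start: int
    sites: tuple[int, ...]
    sequence: tuple[int, ...]


def toy_from_blocks(n: int, blocks: Sequence[tuple[Sequence[int], bool]]) -> ToySystem:
    """Assemble a system from (sequence, is_chain) blocks, left to right."""
    types: list[int] = []
    chain_ids: list[int] = []
    cid = 0
    for seq, is_chain in blocks:
        for t in seq:
            types.append(int(t))
            chain_ids.append(cid if is_chain else FREE)
        if is_chain:
            cid += 1
    return ToySystem(n, tuple(types), tuple(chain_ids))


def build_toy_system(n: int, monomer_counts: Sequence[int],
                     chain_specs: Sequence[ChainSpec] = (),
                     seed: int = 0) -> ToySystem:
    """Deterministically arrange chains and free monomers on a line.

    ``monomer_counts`` gives the number of free monomers per type
    (length n).  Chain copies and free monomers are shuffled together
    with the seeded RNG; random chain sequences are drawn uniformly.
    """
    if len(monomer_counts) != n:
        raise ValueError(f"monomer_counts must have {n} entries")
    if any(c < 0 for c in monomer_counts):
        raise ValueError("monomer_counts must be >= 0")
    rng = random.Random(seed)
    blocks: list[tuple[tuple[int, ...], bool]] = []
    for t, count in enumerate(monomer_counts):
        blocks.extend(((t,), False) for _ in range(count))
    for spec in chain_specs:
        for _ in range(spec.copies):
            if spec.kind == "defined":
                seq = tuple(int(t) for t in spec.sequence)
                if any(t < 0 or t >= n for t in seq):
                    raise ValueError("defined sequence uses a type outside the alphabet")
            else:
                seq = tuple(rng.randrange(n) for _ in range(spec.length))
            blocks.append((seq, True))
    if not blocks:
        raise ValueError("empty system: no monomers and no chains")
    rng.shuffle(blocks)
    return toy_from_blocks(n, blocks)


def sample_walk(system: ToySystem, start: int) -> WalkRecord:
    """Nearest-unvisited-unit walk from ``start`` over the whole line.

    Each step moves to the unvisited site at minimal distance from the
    current one (ties toward the lower index), visiting every unit
    exactly once.
    """
    N = system.N
    if not (0 <= start < N):
        raise ValueError(f"start must lie in [0, {N}), got {start}")
    unvisited = set(range(N))
    cur = start
    order = [cur]
    unvisited.discard(cur)
    while unvisited:
        nxt = min(unvisited, key=lambda s: (abs(s - cur), s))
        order.append(nxt)
        unvisited.discard(nxt)
        cur = nxt
    sites = tuple(order)
    return WalkRecord(start, sites, tuple(system.types[s] for s in sites))


def walk_ensemble_log_weight(systems: Iterable[ToySystem], *,
                             match_composition: bool = True) -> float:
    """ln of the number of distinct walk readouts over the ensemble.

    Enumerates walks from every start of every supplied arrangement and
    counts distinct type sequences D; returns ln D.  All systems must
    share one chain-length spectrum, alphabet and size; with
    ``match_composition`` (the default) the per-type unit counts must
    match too — disable it for ensembles whose sequences are drawn at
    random, where realized counts fluctuate around the shared recipe.
    Used only for ordinal comparisons against the closed forms.
    """
    systems = list(systems)
    if not systems:
        raise ValueError("empty ensemble")
    ref = (systems[0].n, systems[0].N, systems[0].chain_lengths(),
           systems[0].composition() if match_composition else None)
    sequences: set[tuple[int, ...]] = set()
    for sys_ in systems:
        key = (sys_.n, sys_.N, sys_.chain_lengths(),
               sys_.composition() if match_composition else None)
        if key != ref:
            raise ValueError("ensemble members must share composition and chain spec")
        for start in range(sys_.N):
            sequences.add(sample_walk(sys_, start).sequence)
    return math.log(len(sequences))


def multinomial_mixing_entropy(counts: Sequence[int]) -> float:
    """Exact mixing entropy ln(N! / prod N_i!) in units of k."""
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero counts")
    return float(gammaln(total + 1) - sum(gammaln(c + 1) for c in counts))


def explicit_encoding_length(system: ToySystem) -> int:
    """Concrete bit count for the smaller of two literal encodings.

    (a) a census: one counter of ``ceil(log2(1 + max count))`` bits for
    each of the ``n**L`` possible sequences of the common chain length;
    (b) a listing: every chain unit at ``ceil(log2 n)`` bits.
    Requires all chains to share one length L with ``n**L <= 10**6``.
    """
    chains = system.chains()
    if not chains:
        raise ValueError("system has no chains to encode")
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains must all share one length")
    L = lengths.pop()
    if system.n ** L > 10 ** 6:
        raise ValueError(f"enumeration too large: n**L = {system.n ** L}")
    counts: dict[tuple[int, ...], int] = {}
    for c in chains:
        counts[c] = counts.get(c, 0) + 1
    width = math.ceil(math.log2(1 + max(counts.values())))
    census_bits = system.n ** L * width
    bits_per_unit = max(1, math.ceil(math.log2(system.n)))
    listing_bits = sum(len(c) for c in chains) * bits_per_unit
    return min(census_bits, listing_bits)


def canonical_ensembles(n: int = 3, L: int = 3, random_samples: int = 400,
                        seed: int = 0) -> dict[str, list[ToySystem]]:
    """Matched-size ensembles for the four canonical system states.

    All four share N = n * L total units over an n-letter alphabet:

    - ``monomer``: every distinct arrangement of L free monomers per type;
    - ``crystals``: every ordering of n single-type chains of length L;
    - ``defined``: n copies of one shared defined chain (one arrangement);
    - ``random``: n random chains of length L, ``random_samples`` seeded draws.
    """
    if n ** (n * L) < random_samples:
        raise ValueError("alphabet too small for a meaningful random ensemble")
    counts = (L,) * n
    pool = sorted(t for t, c in enumerate(counts) for _ in range(c))
    monomer = [
        toy_from_blocks(n, [((t,), False) for t in perm])
        for perm in sorted(set(itertools.permutations(pool)))
    ]
    crystals = [
        toy_from_blocks(n, [((t,) * L, True) for t in order])
        for order in itertools.permutations(range(n))
    ]
    shared = tuple(range(min(n, L))) + tuple(0 for _ in range(max(0, L - n)))
    defined = [toy_from_blocks(n, [(shared, True)] * n)]
    rng = random.Random(seed)
    random_systems = [
        build_toy_system(n, (0,) * n,
                         [ChainSpec("random", copies=n, length=L)],
                         seed=rng.randrange(2 ** 32))
        for _ in range(random_samples)
    ]
    return {
        "monomer": monomer,
        "crystals": crystals,
        "defined": defined,
        "random": random_systems,
    }
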