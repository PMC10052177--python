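"""Deterministic mutation/selection evolution of a chain population.

The random-chain fraction p decreases at a constant selection rate
(dp/dt, negative) and is punctuated every ``mutation_period`` time
units by a mutation event: a fraction ``f`` of the defined chains is
lost (converted back to random chains, p <- p + f (1 - p)) while the
defined sequence grows by ``length_increment`` units.  Defined chains
stay ``length_ratio`` times as long as random chains throughout.

Order is evaluated from the uniform-composition sequential entropy at
the number-weighted mean chain length

    L_bar = p L_rand + (1 - p) L_def

and complexity from the mixed-population description lengths with the
defined term at L_def and the random census at L_rand.  That
population-to-metric mapping lives in :func:`population_metrics` so
alternative conventions can be swapped in one place.

There is no randomness anywhere: p is piecewise linear in t (selection
is integrated exactly; ``dt`` only sets the output resolution), so
identical configs give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .complexity import ComplexityEstimate, _as_log10, _census_term, _log10_sum
from .entropy import entropy_uniform
from .system_model import AVOGADRO, ParameterError

__all__ = [
    "PopulationState",
    "EvolutionConfig",
    "EvolutionState",
    "EvolutionTrajectory",
    "step_selection",
    "apply_mutation",
    "run_evolution",
    "end_of_cycle_points",
    "population_metrics",
]

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one evolution run (all deterministic)."""

    duration: float = 50.0
    selection_rate: float = -0.01
    mutation_period: float = 5.0
    loss_fraction: float = 0.3
    length_increment: float = 1.0
    length_ratio: float = 2.0
    dt: float = 1.0
    p0: float = 1.0
    L_def0: float = 20.0
    M: float = 10.0
    n: int = 4
    N: float = AVOGADRO

    def __post_init__(self):
        if not self.duration >= 0:
            raise ParameterError("duration", f"must be >= 0, got {self.duration}")
        if not self.mutation_period > 0:
            raise ParameterError("mutation_period", f"must be > 0, got {self.mutation_period}")
        if not (0.0 <= self.loss_fraction <= 1.0):
            raise ParameterError("loss_fraction", f"must lie in [0, 1], got {self.loss_fraction}")
        if not self.length_ratio > 0:
            raise ParameterError("length_ratio", f"must be > 0, got {self.length_ratio}")
        if not (0.0 <= self.p0 <= 1.0):
            raise ParameterError("p0", f"must lie in [0, 1], got {self.p0}")
        if not self.L_def0 >= 1:
            raise ParameterError("L_def0", f"must be >= 1, got {self.L_def0}")
        if not self.dt > 0:
            raise ParameterError("dt", f"must be > 0, got {self.dt}")
        if self.M < 0:
            raise ParameterError("M", f"must be >= 0, got {self.M}")
        if self.n < 1:
            raise ParameterError("n", f"must be >= 1, got {self.n}")
        if not self.N > 0:
            raise ParameterError("N", f"must be > 0, got {self.N}")


@dataclass(frozen=True)
class EvolutionState:
    """One recorded instant of the population and its metrics.

    ``event_flag`` is 'selection' for ordinary samples, 'cycle_end' for
    the state at the end of a selection period (just before the
    mutation fires) and 'mutation' for the post-event state.
    """

    t: float
    p: float
    L_def: float
    L_rand: float
    L_bar: float
    S_r_JK: float
    order_KJ: float
    c1_bits: float
    c2_bits: float
    c_bits: float
    log10_c: float
    strategy: str
    event_flag: str  # 'selection' | 'cycle_end' | 'mutation'


@dataclass(frozen=True)
class EvolutionTrajectory:
    config: EvolutionConfig
    states: tuple[EvolutionState, ...]

    def __iter__(self) -> Iterator[EvolutionState]:
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def initial(self) -> EvolutionState:
        return self.states[0]

    @property
    def final(self) -> EvolutionState:
        return self.states[-1]


def population_metrics(p: float, L_def: float, cfg: EvolutionConfig
                       ) -> tuple[float, float, float, ComplexityEstimate]:
    """Map the (p, L_def) population to (L_rand, L_bar, S_r_JK, complexity).

    Order uses the number-weighted mean length L_bar in the uniform
    entropy form; the complexity estimates keep the defined term at
    L_def and the random census at L_rand:

        c1 = L_def log2 n + n**L_rand log2(p N / (L_bar + M))
        c2 = L_def log2 n + L_rand (p N / (L_bar + M)) log2 n

    with the same census clamp as the static estimators.
    """
    L_rand = L_def / cfg.length_ratio
    L_bar = p * L_rand + (1.0 - p) * L_def
    breakdown = entropy_uniform(cfg.n, cfg.N, max(L_bar, 1.0), cfg.M, p)

    n = cfg.n
    defined_bits = L_def * math.log2(n) if n > 1 else 0.0
    count = p * cfg.N / (L_bar + cfg.M)
    census_val, census_log10 = _census_term(n, L_rand, count)
    c1 = defined_bits + census_val
    log10_c1 = _log10_sum(_as_log10(defined_bits), census_log10)
    listing = L_rand * count * math.log2(n) if n > 1 else 0.0
    c2 = defined_bits + listing
    log10_c2 = _log10_sum(_as_log10(defined_bits), _as_log10(listing))
    if math.isfinite(c1) and math.isfinite(c2):
        strategy = "a" if c1 <= c2 else "b"
    else:
        strategy = "a" if log10_c1 <= log10_c2 else "b"
    est = ComplexityEstimate(c1, c2, log10_c1, log10_c2, strategy)
    return L_rand, L_bar, breakdown.S_r_JK, est


@dataclass
class PopulationState:
    """Minimal simulator state: just (t, p, L_def); metrics are derived."""

    t: float
    p: float
    L_def: float


def step_selection(state: PopulationState, dt: float, rate: float) -> PopulationState:
    """Advance selection exactly over dt: p <- clamp(p + rate*dt, 0, 1)."""
    if dt <= 0:
        raise ParameterError("dt", f"must be > 0, got {dt}")
    return PopulationState(state.t + dt, min(1.0, max(0.0, state.p + rate * dt)), state.L_def)


def apply_mutation(state: PopulationState, f: float, length_increment: float) -> PopulationState:
    """Mutation event: lose a fraction f of defined chains (they become
    random: p <- p + f (1 - p)) and lengthen the defined chain."""
    if not (0.0 <= f <= 1.0):
        raise ParameterError("loss_fraction", f"must lie in [0, 1], got {f}")
    return PopulationState(state.t, state.p + f * (1.0 - state.p), state.L_def + length_increment)


def _record(pop: PopulationState, cfg: EvolutionConfig, flag: str) -> EvolutionState:
    L_rand, L_bar, S_r_JK, est = population_metrics(pop.p, pop.L_def, cfg)
    return EvolutionState(
        t=pop.t, p=pop.p, L_def=pop.L_def, L_rand=L_rand, L_bar=L_bar,
        S_r_JK=S_r_JK, order_KJ=1.0 / S_r_JK,
        c1_bits=est.c1, c2_bits=est.c2, c_bits=est.c,
        log10_c=est.log10_c, strategy=est.strategy, event_flag=flag,
    )


def run_evolution(config: EvolutionConfig) -> EvolutionTrajectory:
    """Alternate exact selection spans with mutation events.

    Within each cycle selection integrates first, then the mutation
    fires at t = k * mutation_period; both the pre-event state (flagged
    'cycle_end') and the post-event state (flagged 'mutation') are
    recorded.  If the duration is not a multiple of the period, the
    final partial span ends in a 'cycle_end' record with no mutation.
    """
    cfg = config
    pop = PopulationState(0.0, cfg.p0, cfg.L_def0)
    states = [_record(pop, cfg, "selection")]
    if cfg.duration == 0:
        return EvolutionTrajectory(cfg, tuple(states))

    next_sample = cfg.dt
    next_event = cfg.mutation_period
    while pop.t < cfg.duration - _TIME_EPS:
        t_stop = min(next_sample, next_event, cfg.duration)
        if t_stop > pop.t + _TIME_EPS:
            pop = step_selection(pop, t_stop - pop.t, cfg.selection_rate)
        at_event = abs(pop.t - next_event) <= _TIME_EPS and next_event <= cfg.duration + _TIME_EPS
        at_end = abs(pop.t - cfg.duration) <= _TIME_EPS
        if at_event:
            states.append(_record(pop, cfg, "cycle_end"))
            pop = apply_mutation(pop, cfg.loss_fraction, cfg.length_increment)
            states.append(_record(pop, cfg, "mutation"))
            next_event += cfg.mutation_period
        elif at_end:
            states.append(_record(pop, cfg, "cycle_end"))
        elif abs(pop.t - next_sample) <= _TIME_EPS:
            states.append(_record(pop, cfg, "selection"))
        if abs(pop.t - next_sample) <= _TIME_EPS:
            next_sample += cfg.dt
    return EvolutionTrajectory(cfg, tuple(states))


def end_of_cycle_points(trajectory: EvolutionTrajectory) -> list[EvolutionState]:
    """States at the end of each selection period, in time order."""
    if not len(trajectory):
        raise ValueError("empty trajectory")
    return [s for s in trajectory if s.event_flag == "cycle_end"]
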