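"""Parameter sweeps producing order-vs-complexity trajectories.

Each sweep varies one parameter of the uniform-composition model while
holding the others at the documented base point (n=4, one mole of
units, L=20, M=10, p=0.5), pairing the sequential-entropy order with
the min-description-length complexity at every grid point.  Grids run
in the direction the source trajectories are drawn: p descending from
1.00 to 0.05, L ascending from 1.0 to 10.5, M descending from 20 to 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .complexity import system_complexity
from .entropy import entropy_uniform
from .system_model import AVOGADRO, ParameterError

__all__ = [
    "SweepPoint",
    "sweep_random_fraction",
    "sweep_chain_length",
    "sweep_monomer_spacing",
    "write_sweep",
    "plot_sweep",
    "DEFAULT_P_GRID",
    "DEFAULT_L_GRID",
    "DEFAULT_M_GRID",
]

# Default grids, in drawing order.
DEFAULT_P_GRID = tuple(round(1.00 - 0.05 * i, 2) for i in range(20))      # 1.00 .. 0.05
DEFAULT_L_GRID = tuple(1.0 + 0.5 * i for i in range(20))                  # 1.0 .. 10.5
DEFAULT_M_GRID = tuple(float(20 - i) for i in range(21))                  # 20 .. 0

CSV_COLUMNS = ("param_name", "param_value", "S_r_JK", "order_KJ",
               "c1_bits", "c2_bits", "c_bits", "log10_c", "strategy")


@dataclass(frozen=True)
class SweepPoint:
    """One grid point: entropy/order paired with the complexity estimate."""

    param_name: str
    param_value: float
    S_r_JK: float
    order_KJ: float
    c1_bits: float
    c2_bits: float
    c_bits: float
    log10_c: float
    strategy: str

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in CSV_COLUMNS}


def _point(param_name: str, value: float, n: int, N: float, L: float, M: float,
           p: float) -> SweepPoint:
    breakdown = entropy_uniform(n, N, L, M, p)
    est = system_complexity(n, L, p, N, M)
    return SweepPoint(
        param_name=param_name,
        param_value=float(value),
        S_r_JK=breakdown.S_r_JK,
        order_KJ=breakdown.order_KJ,
        c1_bits=est.c1,
        c2_bits=est.c2,
        c_bits=est.c,
        log10_c=est.log10_c,
        strategy=est.strategy,
    )


def sweep_random_fraction(n: int = 4, N: float = AVOGADRO, L: float = 20.0,
                          M: float = 10.0,
                          p_grid: Sequence[float] = DEFAULT_P_GRID) -> list[SweepPoint]:
    """Vary the random-chain fraction p over ``p_grid`` (default
    1.00 down to 0.05 in steps of 0.05)."""
    for p in p_grid:
        if not (0.0 <= p <= 1.0):
            raise ParameterError("p_grid", f"values must lie in [0, 1], got {p}")
    return [_point("p", p, n, N, L, M, p) for p in p_grid]


def sweep_chain_length(n: int = 4, N: float = AVOGADRO, p: float = 0.5,
                       M: float = 10.0,
                       L_grid: Sequence[float] = DEFAULT_L_GRID) -> list[SweepPoint]:
    """Vary the mean chain length L over ``L_grid`` (default 1.0 up to
    10.5 in steps of 0.5)."""
    for L in L_grid:
        if L < 1.0:
            raise ParameterError("L_grid", f"values must be >= 1, got {L}")
    return [_point("L", L, n, N, L, M, p) for L in L_grid]


def sweep_monomer_spacing(n: int = 4, N: float = AVOGADRO, L: float = 20.0,
                          p: float = 0.5,
                          M_grid: Sequence[float] = DEFAULT_M_GRID) -> list[SweepPoint]:
    """Vary the monomer spacing M over ``M_grid`` (default 20 down to 0
    in steps of 1)."""
    for M in M_grid:
        if M < 0.0:
            raise ParameterError("M_grid", f"values must be >= 0, got {M}")
    return [_point("M", M, n, N, L, M, p) for M in M_grid]


def write_sweep(points: Iterable[SweepPoint], path, format: str = "csv") -> None:
    """Write sweep points to ``path`` as CSV (header + one row per
    point, preserving sweep order) or as a JSON array."""
    points = list(points)
    if not points:
        raise ValueError("empty sweep: nothing to write")
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for pt in points:
                writer.writerow({k: repr(v) if isinstance(v, float) else v
                                 for k, v in pt.to_dict().items()})
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([pt.to_dict() for pt in points], fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def plot_sweep(points: Sequence[SweepPoint], path) -> None:
    """Optional order-vs-complexity scatter (complexity on a log axis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [10.0 ** pt.log10_c if math.isfinite(pt.log10_c) else 0.0 for pt in points]
    ys = [pt.order_KJ for pt in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, "o-", ms=4)
    ax.set_xscale("log")
    ax.set_xlabel("complexity c (bit)")
    ax.set_ylabel("order 1/S_r (K/J)")
    ax.set_title(f"sweep over {points[0].param_name}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
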