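"""Two-compartment composition model for mixed adipocyte / proliferative-cell cultures.

The model explains why long-term cultures started from a nearly pure adipocyte
preparation can end up dominated by proliferative (non-adipocyte) cells.  It
tracks two compartments in daily (24 h) steps:

* ``adipocyte`` — post-mitotic adipocyte-derived cells.  They never divide and
  lose a fixed fraction per day: ``adipocyte_{n+1} = adipocyte_n * survival``.
* ``other`` — proliferative contaminating cells (preadipocytes, MPPs, ...).
  They suffer the same daily survival but additionally grow with a daily
  growth factor ``g`` determined by their doubling time ``T_d`` (hours):
  ``other_{n+1} = other_n * survival * g`` with ``g = 1 + 24/T_d``.

The quantity of interest is the proliferative ("other") fraction

    other_fraction_n = other_n / (other_n + adipocyte_n) * 100  [percent].

Because survival multiplies both compartments equally it cancels from the
fraction, which therefore has the closed form

    f_n = f0 * g**n / (f0 * g**n + (1 - f0)),

with ``f0`` the initial proliferative fraction.  ``closed_form_fraction`` and
``minimal_initial_fraction`` exploit this cancellation; ``simulate_composition``
iterates the recurrence verbatim, so the two routes cross-check each other.

The daily factor ``1 + 24/T_d`` is a linear within-day approximation of
doubling.  An exponential alternative ``g = 2**(24/T_d)`` is available through
``growth="exponential"`` for sensitivity analyses; the linear form is the
default because it is the model's defining contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationModelParams",
    "CompositionTrajectory",
    "growth_factor",
    "step_composition",
    "simulate_composition",
    "closed_form_fraction",
    "minimal_initial_fraction",
    "sweep_doubling_times",
]

GrowthMode = Literal["linear", "exponential"]


def growth_factor(division_time: float, growth: GrowthMode = "linear") -> float:
    """Daily multiplicative growth factor of the proliferative compartment.

    Parameters
    ----------
    division_time:
        Doubling time in hours; must be positive (``math.inf`` is allowed and
        yields a factor of 1, i.e. no growth).
    growth:
        ``"linear"`` gives ``1 + 24/division_time`` (the model's contract);
        ``"exponential"`` gives ``2**(24/division_time)``.
    """
    if not division_time > 0:
        raise ValueError(f"division_time must be > 0 h, got {division_time!r}")
    if growth == "linear":
        return 1.0 + 24.0 / division_time
    if growth == "exponential":
        return 2.0 ** (24.0 / division_time)
    raise ValueError(f"unknown growth mode {growth!r}")


@dataclass(frozen=True)
class PopulationModelParams:
    """Parameters of the daily composition recurrence.

    Attributes
    ----------
    survival:
        Fraction of each compartment surviving every 24 h period, in (0, 1].
        Applied equally to both compartments (the model's key assumption);
        default 0.99.
    division_time:
        Doubling time of the proliferative compartment in hours; default 24.
    adipocyte_0, other_0:
        Initial abundances (counts or fractions; only their ratio matters for
        the composition). Default 99 / 1, i.e. a 1% proliferative contaminant.
    n_days:
        Number of daily steps to simulate; default 26 (a typical interval from
        tissue digestion to end-of-culture readout).
    growth:
        Within-day growth model, see :func:`growth_factor`.
    """

    survival: float = 0.99
    division_time: float = 24.0
    adipocyte_0: float = 99.0
    other_0: float = 1.0
    n_days: int = 26
    growth: GrowthMode = "linear"

    def __post_init__(self) -> None:
        if not (0.0 < self.survival <= 1.0):
            raise ValueError(f"survival must be in (0, 1], got {self.survival!r}")
        if not self.division_time > 0:
            raise ValueError(f"division_time must be > 0 h, got {self.division_time!r}")
        if self.adipocyte_0 < 0 or self.other_0 < 0:
            raise ValueError("initial abundances must be non-negative")
        if self.adipocyte_0 + self.other_0 <= 0:
            raise ValueError("adipocyte_0 + other_0 must be > 0")
        if self.n_days < 0 or int(self.n_days) != self.n_days:
            raise ValueError(f"n_days must be a non-negative integer, got {self.n_days!r}")

    @property
    def initial_fraction(self) -> float:
        """Initial proliferative fraction ``other_0 / (other_0 + adipocyte_0)``."""
        return self.other_0 / (self.other_0 + self.adipocyte_0)


@dataclass(frozen=True)
class CompositionTrajectory:
    """Day-by-day output of :func:`simulate_composition`."""

    days: np.ndarray          # 0..n_days
    adipocyte: np.ndarray     # abundance per day
    other: np.ndarray         # abundance per day
    other_fraction_pct: np.ndarray  # percent, per day
    params: PopulationModelParams = field(repr=False)

    @property
    def final_fraction_pct(self) -> float:
        return float(self.other_fraction_pct[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "adipocyte": self.adipocyte,
                "other": self.other,
                "other_fraction_pct": self.other_fraction_pct,
            }
        )


def step_composition(
    adipocyte_n: float,
    other_n: float,
    params: PopulationModelParams,
) -> tuple[float, float]:
    """Advance both compartments by one 24 h period.

    Exact arithmetic contract — no rescaling or normalisation:
    ``adipocyte_{n+1} = adipocyte_n * survival`` and
    ``other_{n+1} = other_n * survival * g``.
    """
    if adipocyte_n < 0 or other_n < 0:
        raise ValueError("abundances must be non-negative")
    g = growth_factor(params.division_time, params.growth)
    return adipocyte_n * params.survival, other_n * params.survival * g


def simulate_composition(params: PopulationModelParams) -> CompositionTrajectory:
    """Iterate the daily recurrence and record the composition each day.

    Day 0 records the initial state; day ``n`` the state after ``n`` steps.
    """
    n = int(params.n_days)
    adipocyte = np.empty(n + 1)
    other = np.empty(n + 1)
    adipocyte[0], other[0] = params.adipocyte_0, params.other_0
    for day in range(n):
        adipocyte[day + 1], other[day + 1] = step_composition(
            adipocyte[day], other[day], params
        )
    fraction = other / (other + adipocyte) * 100.0
    return CompositionTrajectory(
        days=np.arange(n + 1),
        adipocyte=adipocyte,
        other=other,
        other_fraction_pct=fraction,
        params=params,
    )


def closed_form_fraction(
    f0: float,
    division_time: float,
    n_days: int,
    growth: GrowthMode = "linear",
) -> float:
    """Proliferative fraction after ``n_days`` days, starting from fraction ``f0``.

    Equal daily survival of both compartments cancels from the fraction, so

        f_n = f0 * g**n / (f0 * g**n + (1 - f0)),   g = growth_factor(T_d).

    Returns a fraction in [0, 1].
    """
    if not (0.0 <= f0 <= 1.0):
        raise ValueError(f"f0 must be in [0, 1], got {f0!r}")
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days!r}")
    g = growth_factor(division_time, growth)
    if f0 == 0.0:
        return 0.0
    if f0 == 1.0:
        return 1.0
    # work in log space to avoid overflow of g**n for long horizons
    log_gn = n_days * math.log(g)
    # f_n = 1 / (1 + (1-f0)/f0 * g**-n)
    return 1.0 / (1.0 + (1.0 - f0) / f0 * math.exp(-log_gn))


def minimal_initial_fraction(
    target_fraction: float,
    division_time: float,
    n_days: int,
    growth: GrowthMode = "linear",
) -> float:
    """Smallest initial fraction ``f0`` reaching ``target_fraction`` by day ``n_days``.

    Exact algebraic inversion of :func:`closed_form_fraction`:

        f0 = F / (g**n * (1 - F) + F)

    For ``n_days = 0`` this reduces to ``f0 = F`` (no growth has occurred).
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError(
            f"target_fraction must be in (0, 1), got {target_fraction!r}"
        )
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days!r}")
    g = growth_factor(division_time, growth)
    gn = g ** n_days
    return target_fraction / (gn * (1.0 - target_fraction) + target_fraction)


def sweep_doubling_times(
    division_times: Sequence[float] | Iterable[float],
    f0: float = 0.01,
    survival: float = 0.99,
    n_days: int = 26,
    growth: GrowthMode = "linear",
) -> pd.DataFrame:
    """Final proliferative percentage as a function of doubling time.

    Runs the full recurrence (not the closed form) once per doubling time and
    tabulates initial and final proliferative percentages.  For fixed
    ``f0 in (0, 1)`` and ``n_days >= 1`` the final percentage is strictly
    decreasing in doubling time.
    """
    times = list(division_times)
    if not times:
        raise ValueError("division_times must be non-empty")
    rows = []
    for dt in times:
        if not dt > 0:
            raise ValueError(f"doubling times must be > 0 h, got {dt!r}")
        params = PopulationModelParams(
            survival=survival,
            division_time=float(dt),
            adipocyte_0=1.0 - f0,
            other_0=f0,
            n_days=n_days,
            growth=growth,
        )
        traj = simulate_composition(params)
        rows.append(
            {
                "division_time_h": float(dt),
                "initial_pct": 100.0 * f0,
                "final_pct": traj.final_fraction_pct,
            }
        )
    return pd.DataFrame(rows)
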