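"""Three-state partitioned-survival cohort engine.

State membership at each cycle start is read directly off the two
survival curves: the progression-free share is S_pfs (clamped by S_os),
the dead share is 1 − S_os, and the progressed-disease share is the
remainder. No transition matrix is estimated; the curves fully determine
occupancy. Costs and utilities are booked at cycle starts with no
half-cycle correction.

The split of the mass leaving the progression-free state between
progression and death is not identified by the two curves alone; deaths
in a cycle are allocated to the progression-free state in proportion to
its share of the surviving cohort at the previous cycle start (capped by
the actual PFS decline), and the remainder of the PFS decline counts as
new progressions. The split only affects one-off per-progression costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .distributions import DistSpec, survival_at

__all__ = ["TimeGrid", "OccupancyTrace", "state_occupancy", "discount_factor"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform cycle-start grid: t_k = k * cycle_days, k = 0..n_cycles-1."""

    cycle_days: float = 21.0
    n_cycles: int = 174

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def cycle_months(self) -> float:
        return 12.0 * self.cycle_days / 365.25

    @property
    def times_months(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_months

    @property
    def times_years(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_years

    @classmethod
    def from_config(cls, config) -> "TimeGrid":
        return cls(cycle_days=config.cycle_days, n_cycles=config.n_cycles)


@dataclass(frozen=True)
class OccupancyTrace:
    """Per-cycle state occupancy, entry counts and discount factors.

    All arrays are indexed by cycle 0..N-1 and refer to cycle starts.
    ``new_progressions[k]`` and ``new_deaths[k]`` are the probability
    mass entering PD and Death between cycle k−1 and cycle k.
    """

    grid: TimeGrid
    p_pfs: np.ndarray
    p_pd: np.ndarray
    p_dead: np.ndarray
    new_progressions: np.ndarray
    new_deaths: np.ndarray
    discount: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_cycles
        for name in ("p_pfs", "p_pd", "p_dead", "new_progressions",
                     "new_deaths", "discount"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        total = self.p_pfs + self.p_pd + self.p_dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state occupancies must sum to 1 at every cycle")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.grid.n_cycles),
                "time_months": self.grid.times_months,
                "p_pfs": self.p_pfs,
                "p_pd": self.p_pd,
                "p_dead": self.p_dead,
                "new_progressions": self.new_progressions,
                "new_deaths": self.new_deaths,
                "discount": self.discount,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def discount_factor(t_years, rate: float):
    """Annual discounting evaluated at cycle start: (1 + rate)^(−t)."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    if rate < 0:
        raise ValueError("negative discount rate")
    out = (1.0 + rate) ** (-t)
    return out if np.ndim(t_years) else float(out)


def _as_survival_values(s, t_months: np.ndarray) -> np.ndarray:
    if isinstance(s, DistSpec):
        vals = np.asarray(survival_at(s, t_months), dtype=float)
    elif callable(s):
        vals = np.asarray(s(t_months), dtype=float)
    else:
        vals = np.asarray(s, dtype=float)
        if vals.shape != t_months.shape:
            raise ValueError("survival array does not match the time grid")
    if np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
        raise ValueError("survival values must lie in [0, 1]")
    return np.clip(vals, 0.0, 1.0)


def state_occupancy(
    s_pfs: DistSpec | Callable | np.ndarray,
    s_os: DistSpec | Callable | np.ndarray,
    grid: TimeGrid,
    discount_rate: float = 0.0,
) -> OccupancyTrace:
    """Partition the cohort over PFS / PD / Death on the cycle grid.

    Survival inputs may be distributions, callables of time in months, or
    precomputed arrays on the grid. Where the PFS curve exceeds the OS
    curve it is clamped (the usual partitioned-survival repair).
    """
    t = grid.times_months
    pfs = _as_survival_values(s_pfs, t)
    os_ = _as_survival_values(s_os, t)
    p_pfs = np.minimum(pfs, os_)
    p_dead = 1.0 - os_
    p_pd = np.maximum(os_ - p_pfs, 0.0)

    new_deaths = np.diff(p_dead, prepend=0.0)
    new_deaths = np.maximum(new_deaths, 0.0)
    decline_pfs = np.maximum(0.0, -np.diff(p_pfs, prepend=1.0))
    pfs_prev = np.concatenate([[1.0], p_pfs[:-1]])
    alive_prev = np.concatenate([[1.0], os_[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        pfs_share = np.where(alive_prev > 0, pfs_prev / alive_prev, 0.0)
    deaths_from_pfs = np.minimum(decline_pfs, new_deaths * pfs_share)
    new_progressions = decline_pfs - deaths_from_pfs

    return OccupancyTrace(
        grid=grid,
        p_pfs=p_pfs,
        p_pd=p_pd,
        p_dead=p_dead,
        new_progressions=new_progressions,
        new_deaths=new_deaths,
        discount=discount_factor(grid.times_years, discount_rate),
    )
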