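"""Costing and QALY accrual rules applied to an occupancy trace.

Booking rules (each unit cost maps to exactly one rule):

* First-line drugs are dispensed at every cycle start spent progression
  free. Induction (4 cycles) carries the platinum doublet; maintenance
  carries pemetrexed (non-squamous) and/or toripalimab. Toripalimab stops
  after the 2-year cap. A mixed-histology cohort weights the squamous and
  non-squamous regimen costs by ``histology_weight_squamous``.
* An administration bundle (one day of physician/IV/care/bed plus the
  three routine labs) is booked per progression-free cycle; CT imaging
  every ``ct_interval_cycles`` cycles.
* Grade >=3 adverse events are one-off: expected cost and a one-cycle
  utility decrement, both booked at cycle 0.
* On progression, the ``subsequent_chemo`` share receives a one-off
  4-cycle docetaxel course (drug + administration bundle); the ``bsc``
  share accrues best-supportive-care cost per PD cycle; in the
  chemotherapy arm the ``crossover_toripalimab`` share receives
  toripalimab per PD cycle while within ``crossover_cap_cycles`` of
  progression. Every PD cycle also books a follow-up visit.
* Terminal care is a one-off cost per death.

Costs and utilities are discounted at cycle starts; no half-cycle
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from .engine import OccupancyTrace, TimeGrid
from .params import AE_NAMES, ArmSpec, CostTable, ModelConfig, UtilityTable

__all__ = [
    "RegimenSchedule",
    "ArmValuation",
    "pfs_cycle_cost",
    "ae_burden",
    "post_progression_cycle_cost",
    "accumulate",
]

COST_COMPONENTS = (
    "drug",
    "administration",
    "adverse_events",
    "post_progression",
    "follow_up",
    "terminal_care",
)


@dataclass(frozen=True)
class RegimenSchedule:
    """Cycle counts defining the protocol phases for one arm."""

    induction_cycles: int
    toripalimab_cap_cycles: int
    subsequent_docetaxel_cycles: int
    crossover_cap_cycles: int

    def __post_init__(self) -> None:
        if self.induction_cycles < 1:
            raise ValueError("induction must last at least one cycle")
        if self.toripalimab_cap_cycles < self.induction_cycles:
            raise ValueError("toripalimab cap shorter than induction")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "RegimenSchedule":
        return cls(
            induction_cycles=config.induction_cycles,
            toripalimab_cap_cycles=config.toripalimab_cap_cycles,
            subsequent_docetaxel_cycles=config.subsequent_docetaxel_cycles,
            crossover_cap_cycles=config.crossover_cap_cycles,
        )


@dataclass(frozen=True)
class ArmValuation:
    """Discounted and undiscounted totals for one arm, by component."""

    arm_id: str
    components: Dict[str, float]
    components_undiscounted: Dict[str, float]
    qalys: float
    qalys_undiscounted: float
    life_years: float

    @property
    def total_cost(self) -> float:
        return float(sum(self.components.values()))

    @property
    def total_cost_undiscounted(self) -> float:
        return float(sum(self.components_undiscounted.values()))

    def to_dict(self) -> dict:
        out = {"arm": self.arm_id, "total_cost": self.total_cost,
               "qalys": self.qalys, "life_years": self.life_years,
               "total_cost_undiscounted": self.total_cost_undiscounted,
               "qalys_undiscounted": self.qalys_undiscounted}
        out.update({f"cost_{k}": v for k, v in self.components.items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def _first_line_drug_cost(
    arm: ArmSpec, schedule: RegimenSchedule, costs: CostTable,
    histology_weight_squamous: float, k: np.ndarray
) -> np.ndarray:
    """Histology-weighted first-line drug cost at cycle indices ``k``."""
    d = costs.drug
    induction = k < schedule.induction_cycles
    tori = (
        np.where(k < schedule.toripalimab_cap_cycles, d["toripalimab"], 0.0)
        if arm.on_immunotherapy
        else 0.0
    )
    non_squamous = np.where(
        induction, d["pemetrexed"] + d["carboplatin"], d["pemetrexed"]
    ) + tori
    squamous = np.where(
        induction, d["nab_paclitaxel"] + d["carboplatin"], 0.0
    ) + tori
    w = histology_weight_squamous
    return w * squamous + (1.0 - w) * non_squamous


def pfs_cycle_cost(
    cycle: int,
    arm: ArmSpec,
    schedule: RegimenSchedule,
    costs: CostTable,
    histology_weight_squamous: float,
    ct_interval_cycles: int = 2,
) -> float:
    """Cost per person-cycle spent progression free at ``cycle``."""
    k = np.asarray([cycle])
    drug = _first_line_drug_cost(arm, schedule, costs, histology_weight_squamous, k)[0]
    admin = costs.cycle_bundle
    if cycle % ct_interval_cycles == 0:
        admin += costs.admin["ct_exam"]
    return float(drug + admin)


def ae_burden(
    arm: ArmSpec,
    costs: CostTable,
    utilities: UtilityTable,
    cycle_years: float,
) -> tuple[float, float]:
    """One-off adverse-event cost and QALY decrement, booked at cycle 0.

    Each patient counts at most once per event type; the disutility
    applies for a single cycle.
    """
    cost = sum(arm.ae_incidence[ae] * costs.ae[ae] for ae in AE_NAMES)
    decrement = (
        sum(arm.ae_incidence[ae] * utilities.ae_disutility[ae] for ae in AE_NAMES)
        * cycle_years
    )
    return float(cost), float(decrement)


@dataclass(frozen=True)
class PdCostRule:
    """Per-cycle and one-off costing of the progressed-disease state."""

    per_pd_cycle: float           # BSC share + follow-up visit, per person-cycle
    crossover_per_cycle: float    # toripalimab for the crossover share, while eligible
    one_time_per_progression: float  # docetaxel course for the subsequent-chemo share


def post_progression_cycle_cost(
    arm: ArmSpec, costs: CostTable, schedule: RegimenSchedule
) -> PdCostRule:
    mix = arm.post_progression_mix
    per_cycle = mix["bsc"] * costs.bsc_per_cycle + costs.follow_up_visit
    crossover = mix["crossover_toripalimab"] * costs.drug["toripalimab"]
    course_cycles = schedule.subsequent_docetaxel_cycles
    one_time = mix["subsequent_chemo"] * course_cycles * (
        costs.drug["docetaxel"] + costs.cycle_bundle
    )
    return PdCostRule(float(per_cycle), float(crossover), float(one_time))


def _crossover_eligible(trace: OccupancyTrace, window_cycles: int) -> np.ndarray:
    """PD mass still within ``window_cycles`` of its progression cycle,
    capped by current PD occupancy (progressors who died drop out)."""
    cum = np.cumsum(trace.new_progressions)
    w = int(window_cycles)
    lagged = np.concatenate([np.zeros(min(w, cum.size)), cum[:-w] if w < cum.size else []])
    recent = cum - lagged
    return np.minimum(trace.p_pd, recent)


def accumulate(
    trace: OccupancyTrace, arm: ArmSpec, config: ModelConfig
) -> ArmValuation:
    """Fold an occupancy trace into discounted costs and QALYs."""
    grid = trace.grid
    if abs(grid.cycle_days - config.cycle_days) > 1e-9 or grid.n_cycles != config.n_cycles:
        raise ValueError("trace grid does not match the configuration")
    schedule = RegimenSchedule.from_config(config)
    costs, utilities = config.costs, config.utilities
    k = np.arange(grid.n_cycles)
    disc = trace.discount

    drug = _first_line_drug_cost(
        arm, schedule, costs, config.histology_weight_squamous, k
    ) * trace.p_pfs
    admin = (
        costs.cycle_bundle
        + np.where(k % config.ct_interval_cycles == 0, costs.admin["ct_exam"], 0.0)
    ) * trace.p_pfs

    rule = post_progression_cycle_cost(arm, costs, schedule)
    eligible = _crossover_eligible(trace, schedule.crossover_cap_cycles)
    bsc = arm.post_progression_mix["bsc"] * costs.bsc_per_cycle * trace.p_pd
    follow_up = costs.follow_up_visit * trace.p_pd
    crossover = rule.crossover_per_cycle * eligible
    courses = rule.one_time_per_progression * trace.new_progressions
    terminal = costs.terminal_care * trace.new_deaths

    ae_cost, ae_decrement = ae_burden(arm, costs, utilities, config.cycle_years)

    per_cycle = {
        "drug": drug,
        "administration": admin,
        "post_progression": bsc + crossover + courses,
        "follow_up": follow_up,
        "terminal_care": terminal,
    }
    components = {name: float(np.sum(disc * arr)) for name, arr in per_cycle.items()}
    components_undisc = {name: float(np.sum(arr)) for name, arr in per_cycle.items()}
    # adverse events are booked at cycle 0, where the discount factor is 1
    components["adverse_events"] = ae_cost
    components_undisc["adverse_events"] = ae_cost
    components = {name: components[name] for name in COST_COMPONENTS}
    components_undisc = {name: components_undisc[name] for name in COST_COMPONENTS}

    utility_per_cycle = config.cycle_years * (
        utilities.u_pfs * trace.p_pfs + utilities.u_pd * trace.p_pd
    )
    qalys = float(np.sum(disc * utility_per_cycle)) - ae_decrement
    qalys_undisc = float(np.sum(utility_per_cycle)) - ae_decrement
    life_years = float(np.sum(config.cycle_years * (1.0 - trace.p_dead)))

    return ArmValuation(
        arm_id=arm.arm_id,
        components=components,
        components_undiscounted=components_undisc,
        qalys=qalys,
        qalys_undiscounted=qalys_undisc,
        life_years=life_years,
    )
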