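"""Cost-effectiveness analysis: base case, one-way and probabilistic
sensitivity analysis, acceptability curves, and histology subgroups.

The probabilistic analysis samples every uncertain parameter from its
assigned family (beta for proportions and utilities, gamma for costs,
normal for body surface area), moment matched to the published point
estimate and range — the range is read as a central 95% interval, so
sd = (high − low)/(2 * 1.96). Toripalimab price and the discount rate are
held fixed. Post-progression shares are sampled independently, each from
its own beta rule, mirroring how the source table parameterises them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TimeGrid, state_occupancy
from .params import ModelConfig, UncertainParam
from .survival import adjust_background_mortality
from .valuation import ArmValuation, accumulate

__all__ = [
    "CEResult",
    "TornadoRow",
    "PsaSample",
    "CeacCurve",
    "icer",
    "run_arm",
    "run_base_case",
    "owsa",
    "psa",
    "ceac",
    "ceac_crossing",
    "run_subgroup",
]

DOMINANCE_FLAGS = ("none", "intervention_dominant", "intervention_dominated",
                   "undefined", "equivalent")


def icer(delta_cost: float, delta_qalys: float) -> tuple[float, str]:
    """Incremental cost-effectiveness ratio with dominance handling.

    Returns ``(value, flag)``. The ratio is only formed when the
    intervention adds or removes QALYs; otherwise a flag is returned and
    the value is NaN (or 0 when both increments vanish as cost falls).
    """
    if delta_qalys == 0.0:
        if delta_cost == 0.0:
            return 0.0, "equivalent"
        return math.nan, "undefined"
    if delta_qalys > 0 and delta_cost < 0:
        return math.nan, "intervention_dominant"
    if delta_qalys < 0 and delta_cost > 0:
        return math.nan, "intervention_dominated"
    if delta_cost == 0.0:
        return 0.0, "none"
    return delta_cost / delta_qalys, "none"


@dataclass(frozen=True)
class CEResult:
    """Paired arm valuations and their incremental comparison."""

    intervention: ArmValuation
    comparator: ArmValuation
    delta_cost: float
    delta_qalys: float
    icer: float
    dominance: str

    @classmethod
    def from_valuations(cls, intervention: ArmValuation,
                        comparator: ArmValuation) -> "CEResult":
        dc = intervention.total_cost - comparator.total_cost
        de = intervention.qalys - comparator.qalys
        value, flag = icer(dc, de)
        return cls(intervention, comparator, dc, de, value, flag)

    def to_frame(self) -> pd.DataFrame:
        """Base-case style summary table, one row per arm."""
        rows = [
            {
                "arm": self.comparator.arm_id,
                "cost": self.comparator.total_cost,
                "qalys": self.comparator.qalys,
                "delta_cost": math.nan,
                "delta_qalys": math.nan,
                "icer": math.nan,
            },
            {
                "arm": self.intervention.arm_id,
                "cost": self.intervention.total_cost,
                "qalys": self.intervention.qalys,
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
                "icer": self.icer,
            },
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention.to_dict(),
            "comparator": self.comparator.to_dict(),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def run_arm(config: ModelConfig, arm_id: str) -> ArmValuation:
    """Occupancy trace plus valuation for one arm under a configuration."""
    trace = _arm_trace(config, arm_id)
    return accumulate(trace, config.arms[arm_id], config)


def _arm_trace(config: ModelConfig, arm_id: str):
    arm = config.arms[arm_id]
    grid = TimeGrid.from_config(config)
    t = grid.times_months
    age0 = config.demography.starting_age
    s_os = adjust_background_mortality(arm.os_dist, config.life_table, age0, t)
    s_pfs = adjust_background_mortality(arm.pfs_dist, config.life_table, age0, t)
    return state_occupancy(s_pfs, s_os, grid, discount_rate=config.discount_rate)


def run_base_case(config: ModelConfig) -> CEResult:
    """Deterministic cost-effectiveness comparison of the two arms."""
    return CEResult.from_valuations(
        run_arm(config, "tc"), run_arm(config, "chemo")
    )


# ---------------------------------------------------------------------------
# one-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    path: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def owsa(
    config: ModelConfig, rules: Sequence[UncertainParam] | None = None
) -> list[TornadoRow]:
    """One-way sensitivity analysis over each rule's [low, high] range.

    Each parameter is perturbed alone, the base configuration is restored
    between parameters, and rows come back sorted by ICER span,
    descending. Parameters fixed in the PSA (toripalimab price, discount
    rate) still appear here when their printed range is non-degenerate.
    """
    if rules is None:
        rules = config.uncertain
    rows = []
    for rule in rules:
        icers = {}
        for bound, value in (("low", rule.low), ("high", rule.high)):
            perturbed = config.copy()
            perturbed.set_param(rule.path, value)
            icers[bound] = run_base_case(perturbed).icer
        rows.append(
            TornadoRow(rule.name, rule.path, rule.low, rule.high,
                       icers["low"], icers["high"])
        )
    rows.sort(key=lambda r: -r.span)
    return rows


def tornado_frame(rows: Iterable[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "path": r.path,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_low,
                "icer_high": r.icer_high,
                "span": r.span,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaSample:
    index: int
    values: dict  # path -> sampled value
    result: CEResult


def _moment_matched_sampler(rule: UncertainParam, point: float):
    """Build a sampler for one rule; returns None for fixed/degenerate rules."""
    if rule.family == "fixed":
        return None
    sd = (rule.high - rule.low) / (2.0 * 1.959963984540054)
    if sd == 0.0:
        return None
    var = sd * sd
    if rule.family == "beta":
        m = min(max(point, 1e-9), 1 - 1e-9)
        cap = m * (1.0 - m)
        if var >= cap:
            warnings.warn(
                f"beta variance for {rule.name!r} exceeds m(1-m); clipped"
            )
            var = 0.95 * cap
        nu = cap / var - 1.0
        a, b = m * nu, (1.0 - m) * nu
        return lambda rng: float(rng.beta(a, b))
    if rule.family == "gamma":
        shape = point * point / var
        scale = var / point
        return lambda rng: float(rng.gamma(shape, scale))
    if rule.family == "normal":
        a = (0.0 - point) / sd  # truncate at zero
        dist = stats.truncnorm(a, np.inf, loc=point, scale=sd)
        return lambda rng: float(dist.rvs(random_state=rng))
    raise ValueError(f"unsupported PSA family {rule.family!r}")


def psa(
    config: ModelConfig,
    n_draws: int | None = None,
    seed: int | None = None,
    rules: Sequence[UncertainParam] | None = None,
) -> list[PsaSample]:
    """Monte Carlo parameter uncertainty analysis.

    Survival distributions, toripalimab price and the discount rate stay
    at their base values, so the occupancy traces are computed once and
    re-valued under each draw. Reproducible given the seed.
    """
    if n_draws is None:
        n_draws = config.psa_n_draws
    if seed is None:
        seed = config.psa_seed
    if rules is None:
        rules = config.uncertain
    rng = np.random.default_rng(seed)

    samplers = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # printed-range quirks already documented
        for rule in rules:
            sampler = _moment_matched_sampler(rule, config.get_param(rule.path))
            if sampler is not None:
                samplers.append((rule, sampler))

    traces = {arm_id: _arm_trace(config, arm_id) for arm_id in config.arms}
    samples = []
    for i in range(n_draws):
        draw = config.copy()
        values = {}
        for rule, sampler in samplers:
            value = sampler(rng)
            draw.set_param(rule.path, value)
            values[rule.path] = value
        result = CEResult.from_valuations(
            accumulate(traces["tc"], draw.arms["tc"], draw),
            accumulate(traces["chemo"], draw.arms["chemo"], draw),
        )
        samples.append(PsaSample(i, values, result))
    return samples


def psa_frame(samples: Sequence[PsaSample]) -> pd.DataFrame:
    """Draws as a table: incremental results plus every sampled value."""
    rows = []
    for s in samples:
        row = {
            "draw": s.index,
            "delta_cost": s.result.delta_cost,
            "delta_qalys": s.result.delta_qalys,
            "icer": s.result.icer,
            "cost_tc": s.result.intervention.total_cost,
            "cost_chemo": s.result.comparator.total_cost,
            "qalys_tc": s.result.intervention.qalys,
            "qalys_chemo": s.result.comparator.qalys,
        }
        row.update(s.values)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# acceptability curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CeacCurve:
    """Probability of positive net monetary benefit along a WTP grid."""

    wtp: np.ndarray
    acceptance: np.ndarray

    def __post_init__(self) -> None:
        if self.wtp.shape != self.acceptance.shape:
            raise ValueError("wtp and acceptance must align")
        if np.any((self.acceptance < 0) | (self.acceptance > 1)):
            raise ValueError("acceptance probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "acceptance": self.acceptance})


DEFAULT_WTP_GRID = np.arange(0.0, 60000.0 + 250.0, 250.0)


def ceac(samples: Sequence[PsaSample], wtp_grid=None) -> CeacCurve:
    """Acceptance(WTP) = share of draws with WTP * dE − dC > 0."""
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    dc = np.array([s.result.delta_cost for s in samples])
    de = np.array([s.result.delta_qalys for s in samples])
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    return CeacCurve(grid, (nmb > 0).mean(axis=1))


def ceac_crossing(curve: CeacCurve, level: float = 0.5) -> float | None:
    """Smallest WTP at which acceptance reaches ``level``.

    Linear interpolation between the bracketing grid points; ``None``
    when the level is never reached on the grid.
    """
    acc, wtp = curve.acceptance, curve.wtp
    idx = np.nonzero(acc >= level)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(wtp[0])
    a0, a1 = acc[i - 1], acc[i]
    if a1 == a0:
        return float(wtp[i])
    frac = (level - a0) / (a1 - a0)
    return float(wtp[i - 1] + frac * (wtp[i] - wtp[i - 1]))


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------


def run_subgroup(config: ModelConfig, histology: str) -> CEResult:
    """Run a histology subgroup with the matching single-histology regimen.

    The caller must supply subgroup survival distributions on the arms
    (the published subgroup parameters live outside the base-case table);
    this function only forces the histology weight to 0 or 1 and reruns
    the engine.
    """
    if histology not in ("squamous", "non_squamous"):
        raise ValueError("histology must be 'squamous' or 'non_squamous'")
    if not config.arms:
        raise ValueError(
            "subgroup run needs a configuration with subgroup survival "
            "distributions on both arms; supply them in the config file"
        )
    sub = config.copy()
    sub.histology_weight_squamous = 1.0 if histology == "squamous" else 0.0
    return run_base_case(sub)
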