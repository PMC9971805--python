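"""Typed model parameters, configuration I/O and the published base case.

Every quantity that drives the model — survival distributions, per-cycle
drug and administration costs, adverse-event incidences/costs/disutilities,
state utilities, post-progression treatment mix, discounting — lives on a
:class:`ModelConfig`. Configurations round-trip losslessly through a
schema-versioned YAML file, and :func:`base_case_config` reproduces the
published base case for first-line toripalimab + chemotherapy versus
chemotherapy alone in advanced NSCLC.

Uncertain parameters carry an :class:`UncertainParam` rule (distribution
family, point, low, high) used by both one-way and probabilistic
sensitivity analysis; parameters are addressed by dotted paths such as
``costs.drug.pemetrexed`` or ``arms.chemo.post_progression_mix.crossover_toripalimab``.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .distributions import DistSpec
from .survival import LifeTable

SCHEMA_VERSION = 1

AE_NAMES = ("anemia", "leukopenia", "neutropenia", "thrombocytopenia")
MIX_KEYS = ("crossover_toripalimab", "subsequent_chemo", "bsc")
ARM_IDS = ("tc", "chemo")

DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema or an invariant."""


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ConfigError(f"{name} must be non-negative, got {value}")


@dataclass
class UtilityTable:
    """Annual health-state utilities and one-off adverse-event disutilities."""

    u_pfs: float = 0.80
    u_pd: float = 0.32
    u_death: float = 0.0
    ae_disutility: dict = field(
        default_factory=lambda: {
            "anemia": 0.07,
            "leukopenia": 0.20,
            "neutropenia": 0.20,
            "thrombocytopenia": 0.11,
        }
    )

    def validate(self) -> None:
        for name in ("u_pfs", "u_pd", "u_death"):
            _check_unit(f"utilities.{name}", getattr(self, name))
        if self.u_death != 0.0:
            raise ConfigError("utility of death must be 0")
        for ae in AE_NAMES:
            if ae not in self.ae_disutility:
                raise ConfigError(f"utilities.ae_disutility missing {ae!r}")
            _check_unit(f"utilities.ae_disutility.{ae}", self.ae_disutility[ae])


@dataclass
class CostTable:
    """Unit costs in 2022 USD, organised by booking rule.

    ``drug`` entries are per treatment cycle; ``ae`` entries are one-off
    per event; ``admin`` entries are per exam or per day; the remainder
    are one-off (terminal care) or per cycle (BSC, follow-up visit).
    """

    drug: dict = field(
        default_factory=lambda: {
            "toripalimab": 375.0,
            "carboplatin": 55.18,
            "nab_paclitaxel": 122.73,
            "pemetrexed": 841.48,
            "docetaxel": 31.60,
        }
    )
    ae: dict = field(
        default_factory=lambda: {
            "anemia": 571.98,
            "leukopenia": 451.11,
            "neutropenia": 496.46,
            "thrombocytopenia": 3820.77,
        }
    )
    admin: dict = field(
        default_factory=lambda: {
            "ct_exam": 56.05,
            "blood_biochemistry": 45.34,
            "blood_test": 3.03,
            "urinalysis": 0.61,
            "physician_per_day": 3.03,
            "iv_per_day": 1.67,
            "care_per_day": 3.63,
            "bed_per_day": 6.36,
        }
    )
    terminal_care: float = 2241.18
    bsc_per_cycle: float = 122.18
    follow_up_visit: float = 77.01

    def validate(self) -> None:
        for group in ("drug", "ae", "admin"):
            for key, value in getattr(self, group).items():
                _check_nonneg(f"costs.{group}.{key}", value)
        for name in ("terminal_care", "bsc_per_cycle", "follow_up_visit"):
            _check_nonneg(f"costs.{name}", getattr(self, name))

    @property
    def cycle_bundle(self) -> float:
        """Per-treatment-cycle administration bundle: one day of physician,
        IV, care and bed plus one blood test, biochemistry panel and
        urinalysis. CT imaging is booked separately on its own interval."""
        a = self.admin
        return (
            a["physician_per_day"] + a["iv_per_day"] + a["care_per_day"]
            + a["bed_per_day"] + a["blood_test"] + a["blood_biochemistry"]
            + a["urinalysis"]
        )


@dataclass
class ArmSpec:
    """One treatment strategy: survival model, toxicity and downstream care."""

    arm_id: str
    pfs_dist: DistSpec
    os_dist: DistSpec
    ae_incidence: dict
    post_progression_mix: dict
    on_immunotherapy: bool

    def validate(self) -> None:
        if self.arm_id not in ARM_IDS:
            raise ConfigError(f"arm_id must be one of {ARM_IDS}, got {self.arm_id!r}")
        for ae in AE_NAMES:
            if ae not in self.ae_incidence:
                raise ConfigError(f"arms.{self.arm_id}.ae_incidence missing {ae!r}")
            _check_unit(f"arms.{self.arm_id}.ae_incidence.{ae}", self.ae_incidence[ae])
        for key in MIX_KEYS:
            if key not in self.post_progression_mix:
                raise ConfigError(
                    f"arms.{self.arm_id}.post_progression_mix missing {key!r}"
                )
            _check_unit(
                f"arms.{self.arm_id}.post_progression_mix.{key}",
                self.post_progression_mix[key],
            )
        total = sum(self.post_progression_mix[k] for k in MIX_KEYS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"arms.{self.arm_id}.post_progression_mix must sum to 1, got {total}"
            )


@dataclass
class Demography:
    """Cohort description. Body surface area and creatinine clearance are
    carried as metadata (Table prices are already per cycle) and do not
    rescale drug costs; starting age anchors background mortality."""

    body_surface_area: float = 1.72
    creatinine_clearance: float = 70.0
    starting_age: float = 61.0

    def validate(self) -> None:
        for name in ("body_surface_area", "creatinine_clearance", "starting_age"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"demography.{name} must be positive")


@dataclass
class UncertainParam:
    """Sensitivity-analysis rule for one parameter.

    ``family`` is the PSA sampling distribution (beta, gamma, normal or
    fixed); ``low``/``high`` bound both the one-way analysis and the
    moment match (interpreted as a central 95% interval). Rules with
    ``family == 'fixed'`` are excluded from the PSA but still appear in
    the tornado when their range is non-degenerate.
    """

    name: str
    path: str
    family: str
    low: float
    high: float

    def validate(self, config: "ModelConfig") -> None:
        if self.family not in ("beta", "gamma", "normal", "fixed"):
            raise ConfigError(f"psa family for {self.name!r} must be "
                              "beta/gamma/normal/fixed")
        if self.low > self.high:
            raise ConfigError(f"psa range for {self.name!r} has low > high")
        point = config.get_param(self.path)
        if self.family != "fixed" and not (self.low <= point <= self.high):
            # one printed range in the source table does not bracket its
            # point estimate; keep the row verbatim but flag it
            warnings.warn(
                f"range [{self.low}, {self.high}] for {self.name!r} does not "
                f"bracket the point estimate {point}; sampling around the point"
            )


@dataclass
class ModelConfig:
    """Everything needed for one cost-effectiveness run."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate: float = 0.05
    toripalimab_cap_years: float = 2.0
    induction_cycles: int = 4
    subsequent_docetaxel_cycles: int = 4
    crossover_cap_cycles: int = 34
    ct_interval_cycles: int = 2
    histology_weight_squamous: float = 0.5
    wtp_per_capita_gdp: float = 12269.0
    psa_n_draws: int = 1000
    psa_seed: int = 2023
    demography: Demography = field(default_factory=Demography)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    arms: dict = field(default_factory=dict)  # arm_id -> ArmSpec
    life_table: LifeTable | None = None
    uncertain: list = field(default_factory=list)  # list[UncertainParam]

    # -- invariants ------------------------------------------------------
    def validate(self) -> "ModelConfig":
        if self.cycle_days <= 0:
            raise ConfigError("cycle_days must be positive")
        if self.horizon_years <= 0:
            raise ConfigError("horizon_years must be positive")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ConfigError("discount_rate must lie in [0, 1]")
        _check_unit("histology_weight_squamous", self.histology_weight_squamous)
        if self.induction_cycles < 1:
            raise ConfigError("induction_cycles must be at least 1")
        if self.toripalimab_cap_cycles < self.induction_cycles:
            raise ConfigError("toripalimab cap shorter than induction")
        if set(self.arms) != set(ARM_IDS):
            raise ConfigError(f"exactly two arms {ARM_IDS} required, "
                              f"got {sorted(self.arms)}")
        self.demography.validate()
        self.costs.validate()
        self.utilities.validate()
        for arm in self.arms.values():
            arm.validate()
        for rule in self.uncertain:
            rule.validate(self)
        return self

    # -- derived quantities ---------------------------------------------
    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR * MONTHS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        """Grid points: cycle starts 0..N where N full cycles fit the horizon."""
        return int(math.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_days)) + 1

    @property
    def toripalimab_cap_cycles(self) -> int:
        """Number of cycle starts at which toripalimab is still dispensed."""
        return int(math.floor(self.toripalimab_cap_years * DAYS_PER_YEAR / self.cycle_days))

    @property
    def wtp_threshold(self) -> float:
        """Prespecified willingness to pay: 3x GDP per capita."""
        return 3.0 * self.wtp_per_capita_gdp

    # -- parameter addressing -------------------------------------------
    def get_param(self, path: str) -> float:
        obj: Any = self
        for part in path.split("."):
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        return obj

    def set_param(self, path: str, value: float) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if isinstance(obj, dict):
            if parts[-1] not in obj:
                raise KeyError(path)
            obj[parts[-1]] = value
        else:
            if not hasattr(obj, parts[-1]):
                raise AttributeError(path)
            setattr(obj, parts[-1], value)

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# published base case
# ---------------------------------------------------------------------------

# Histology cost weight and crossover-toripalimab duration are not reported
# in the source table. Both were calibrated once, by least squares against
# the published pooled base-case summaries (arm totals and incremental
# cost), subject to reproducing the published ranking of one-way
# sensitivity drivers; see docs/methods.md. They are ordinary config fields
# and can be overridden in any configuration file.
CALIBRATED_SQUAMOUS_WEIGHT = 0.243
CALIBRATED_CROSSOVER_CAP_CYCLES = 24


def _pct20(x: float) -> tuple[float, float]:
    return 0.8 * x, 1.2 * x


def _default_uncertain() -> list[UncertainParam]:
    rows: list[tuple[str, str, str, float, float]] = [
        # proportions of subsequent care
        ("Subsequent chemotherapy proportion, TC arm",
         "arms.tc.post_progression_mix.subsequent_chemo", "beta", 0.409, 0.613),
        ("BSC proportion, TC arm",
         "arms.tc.post_progression_mix.bsc", "beta", 0.3912, 0.5868),
        ("Crossover proportion, chemotherapy arm",
         "arms.chemo.post_progression_mix.crossover_toripalimab", "beta", 0.4304, 0.6456),
        ("Subsequent chemotherapy proportion, chemotherapy arm",
         "arms.chemo.post_progression_mix.subsequent_chemo", "beta", 0.236, 0.354),
        ("BSC proportion, chemotherapy arm",
         "arms.chemo.post_progression_mix.bsc", "beta", 0.1336, 0.2004),
        # grade >=3 AE incidences
        ("Anemia incidence, TC arm", "arms.tc.ae_incidence.anemia", "beta", 0.2392, 0.3588),
        ("Leukopenia incidence, TC arm", "arms.tc.ae_incidence.leukopenia", "beta", 0.2856, 0.4284),
        ("Neutropenia incidence, TC arm", "arms.tc.ae_incidence.neutropenia", "beta", 0.444, 0.666),
        ("Thrombocytopenia incidence, TC arm", "arms.tc.ae_incidence.thrombocytopenia", "beta", 0.1376, 0.2064),
        ("Anemia incidence, chemotherapy arm", "arms.chemo.ae_incidence.anemia", "beta", 0.2872, 0.4308),
        ("Leukopenia incidence, chemotherapy arm", "arms.chemo.ae_incidence.leukopenia", "beta", 0.3336, 0.5004),
        ("Neutropenia incidence, chemotherapy arm", "arms.chemo.ae_incidence.neutropenia", "beta", 0.4304, 0.6456),
        ("Thrombocytopenia incidence, chemotherapy arm", "arms.chemo.ae_incidence.thrombocytopenia", "beta", 0.1432, 0.2148),
        # utilities and disutilities
        ("Utility of PFS state", "utilities.u_pfs", "beta", 0.64, 0.96),
        ("Utility of PD state", "utilities.u_pd", "beta", 0.26, 0.38),
        ("Anemia disutility", "utilities.ae_disutility.anemia", "beta", 0.058, 0.088),
        ("Leukopenia disutility", "utilities.ae_disutility.leukopenia", "beta", 0.112, 0.168),
        ("Neutropenia disutility", "utilities.ae_disutility.neutropenia", "beta", 0.16, 0.24),
        ("Thrombocytopenia disutility", "utilities.ae_disutility.thrombocytopenia", "beta", 0.086, 0.130),
        # drug costs (toripalimab price can only slide down; fixed in PSA)
        ("Toripalimab cost per cycle", "costs.drug.toripalimab", "fixed", 300.0, 375.0),
        ("Carboplatin cost per cycle", "costs.drug.carboplatin", "gamma", 44.15, 66.22),
        ("Nab-paclitaxel cost per cycle", "costs.drug.nab_paclitaxel", "gamma", 98.182, 147.273),
        ("Pemetrexed cost per cycle", "costs.drug.pemetrexed", "gamma", 673.18, 1009.78),
        ("Docetaxel cost per cycle", "costs.drug.docetaxel", "gamma", 25.28, 37.93),
        # AE unit costs
        ("Anemia cost per event", "costs.ae.anemia", "gamma", 457.58, 686.38),
        ("Leukopenia cost per event", "costs.ae.leukopenia", "gamma", 360.89, 541.33),
        ("Neutropenia cost per event", "costs.ae.neutropenia", "gamma", 397.17, 595.75),
        ("Thrombocytopenia cost per event", "costs.ae.thrombocytopenia", "gamma", 3056.62, 4584.92),
        # administration costs
        ("CT examination cost", "costs.admin.ct_exam", "gamma", 44.84, 67.27),
        ("Blood biochemistry cost", "costs.admin.blood_biochemistry", "gamma", 36.27, 54.41),
        ("Blood test cost", "costs.admin.blood_test", "gamma", 2.42, 3.63),
        ("Urinalysis cost", "costs.admin.urinalysis", "gamma", 0.49, 0.73),
        ("Physician fee per day", "costs.admin.physician_per_day", "gamma", 2.42, 3.63),
        ("Intravenous injection cost per day", "costs.admin.iv_per_day", "gamma", 1.33, 2.00),
        ("Care cost per day", "costs.admin.care_per_day", "gamma", 2.91, 4.36),
        ("Bed cost per day", "costs.admin.bed_per_day", "gamma", 5.09, 7.63),
        ("Terminal care cost", "costs.terminal_care", "gamma", 1792.94, 2689.41),
        ("BSC cost per cycle", "costs.bsc_per_cycle", "gamma", 97.74, 146.62),
        ("Follow-up visit cost", "costs.follow_up_visit", "gamma", 61.61, 92.41),
        # demography (sampled but inert: prices are already per cycle)
        ("Body surface area", "demography.body_surface_area", "normal", 1.38, 2.06),
        # discount rate: fixed in PSA, 0-8% in the tornado
        ("Discount rate", "discount_rate", "fixed", 0.0, 0.08),
    ]
    return [UncertainParam(name, path, fam, lo, hi) for name, path, fam, lo, hi in rows]


def base_case_config(life_table: LifeTable | None = None) -> ModelConfig:
    """The published pooled-NSCLC base case, verbatim.

    If no life table is passed, a synthetic Gompertz schedule approximating
    US adult mortality is generated (see :mod:`psmcea.synthetic`).
    """
    if life_table is None:
        from .synthetic import default_life_table

        life_table = default_life_table()
    arms = {
        "tc": ArmSpec(
            arm_id="tc",
            pfs_dist=DistSpec("lognormal", (2.262, 0.950)),
            os_dist=DistSpec("loglogistic", (1.510, 25.348)),
            ae_incidence={
                "anemia": 0.299,
                "leukopenia": 0.357,
                "neutropenia": 0.555,
                "thrombocytopenia": 0.172,
            },
            post_progression_mix={
                "crossover_toripalimab": 0.0,
                "subsequent_chemo": 0.511,
                "bsc": 0.489,
            },
            on_immunotherapy=True,
        ),
        "chemo": ArmSpec(
            arm_id="chemo",
            pfs_dist=DistSpec("loglogistic", (2.489, 6.089)),
            os_dist=DistSpec("lognormal", (2.897, 0.791)),
            ae_incidence={
                "anemia": 0.359,
                "leukopenia": 0.417,
                "neutropenia": 0.538,
                "thrombocytopenia": 0.179,
            },
            post_progression_mix={
                "crossover_toripalimab": 0.538,
                "subsequent_chemo": 0.295,
                "bsc": 0.167,
            },
            on_immunotherapy=False,
        ),
    }
    cfg = ModelConfig(
        histology_weight_squamous=CALIBRATED_SQUAMOUS_WEIGHT,
        crossover_cap_cycles=CALIBRATED_CROSSOVER_CAP_CYCLES,
        arms=arms,
        life_table=life_table,
        uncertain=_default_uncertain(),
    )
    with warnings.catch_warnings():
        # the printed leukopenia-disutility range does not bracket its point
        warnings.simplefilter("ignore")
        cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# configuration file I/O
# ---------------------------------------------------------------------------


def _dist_to_dict(d: DistSpec) -> dict:
    return {"family": d.family, "params": list(d.params)}


def _dist_from_dict(obj: dict, where: str) -> DistSpec:
    _require_keys(obj, {"family", "params"}, where)
    try:
        return DistSpec(obj["family"], tuple(obj["params"]))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _require_keys(obj: dict, allowed: set, where: str, required: set | None = None) -> None:
    if not isinstance(obj, dict):
        raise ConfigError(f"{where} must be a mapping")
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = (required if required is not None else allowed) - set(obj)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "model": {
            "cycle_days": config.cycle_days,
            "horizon_years": config.horizon_years,
            "discount_rate": config.discount_rate,
            "toripalimab_cap_years": config.toripalimab_cap_years,
            "induction_cycles": config.induction_cycles,
            "subsequent_docetaxel_cycles": config.subsequent_docetaxel_cycles,
            "crossover_cap_cycles": config.crossover_cap_cycles,
            "ct_interval_cycles": config.ct_interval_cycles,
            "histology_weight_squamous": config.histology_weight_squamous,
            "wtp_per_capita_gdp": config.wtp_per_capita_gdp,
            "psa_n_draws": config.psa_n_draws,
            "psa_seed": config.psa_seed,
        },
        "demography": asdict(config.demography),
        "costs": asdict(config.costs),
        "utilities": asdict(config.utilities),
        "arms": {
            arm_id: {
                "pfs_dist": _dist_to_dict(arm.pfs_dist),
                "os_dist": _dist_to_dict(arm.os_dist),
                "ae_incidence": dict(arm.ae_incidence),
                "post_progression_mix": dict(arm.post_progression_mix),
                "on_immunotherapy": arm.on_immunotherapy,
            }
            for arm_id, arm in config.arms.items()
        },
        "life_table": {
            "ages": list(config.life_table.ages),
            "q": list(config.life_table.q),
        },
        "uncertain": [asdict(rule) for rule in config.uncertain],
    }


def config_from_dict(data: dict) -> ModelConfig:
    _require_keys(
        data,
        {"schema", "model", "demography", "costs", "utilities", "arms",
         "life_table", "uncertain"},
        "config",
    )
    if data["schema"] != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {data['schema']!r}")

    m = data["model"]
    _require_keys(
        m,
        {"cycle_days", "horizon_years", "discount_rate", "toripalimab_cap_years",
         "induction_cycles", "subsequent_docetaxel_cycles", "crossover_cap_cycles",
         "ct_interval_cycles", "histology_weight_squamous", "wtp_per_capita_gdp",
         "psa_n_draws", "psa_seed"},
        "model",
    )
    d = data["demography"]
    _require_keys(d, {"body_surface_area", "creatinine_clearance", "starting_age"},
                  "demography")
    c = data["costs"]
    _require_keys(c, {"drug", "ae", "admin", "terminal_care", "bsc_per_cycle",
                      "follow_up_visit"}, "costs")
    u = data["utilities"]
    _require_keys(u, {"u_pfs", "u_pd", "u_death", "ae_disutility"}, "utilities")

    arms = {}
    if set(data["arms"]) != set(ARM_IDS):
        raise ConfigError(f"arms must be exactly {ARM_IDS}")
    for arm_id, a in data["arms"].items():
        _require_keys(
            a,
            {"pfs_dist", "os_dist", "ae_incidence", "post_progression_mix",
             "on_immunotherapy"},
            f"arms.{arm_id}",
        )
        arms[arm_id] = ArmSpec(
            arm_id=arm_id,
            pfs_dist=_dist_from_dict(a["pfs_dist"], f"arms.{arm_id}.pfs_dist"),
            os_dist=_dist_from_dict(a["os_dist"], f"arms.{arm_id}.os_dist"),
            ae_incidence={k: float(v) for k, v in a["ae_incidence"].items()},
            post_progression_mix={k: float(v) for k, v in a["post_progression_mix"].items()},
            on_immunotherapy=bool(a["on_immunotherapy"]),
        )

    lt = data["life_table"]
    _require_keys(lt, {"ages", "q"}, "life_table")
    try:
        life_table = LifeTable(tuple(lt["ages"]), tuple(lt["q"]))
    except ValueError as exc:
        raise ConfigError(f"life_table: {exc}") from exc

    uncertain = []
    for row in data["uncertain"]:
        _require_keys(row, {"name", "path", "family", "low", "high"}, "uncertain[]")
        uncertain.append(
            UncertainParam(row["name"], row["path"], row["family"],
                           float(row["low"]), float(row["high"]))
        )

    cfg = ModelConfig(
        cycle_days=float(m["cycle_days"]),
        horizon_years=float(m["horizon_years"]),
        discount_rate=float(m["discount_rate"]),
        toripalimab_cap_years=float(m["toripalimab_cap_years"]),
        induction_cycles=int(m["induction_cycles"]),
        subsequent_docetaxel_cycles=int(m["subsequent_docetaxel_cycles"]),
        crossover_cap_cycles=int(m["crossover_cap_cycles"]),
        ct_interval_cycles=int(m["ct_interval_cycles"]),
        histology_weight_squamous=float(m["histology_weight_squamous"]),
        wtp_per_capita_gdp=float(m["wtp_per_capita_gdp"]),
        psa_n_draws=int(m["psa_n_draws"]),
        psa_seed=int(m["psa_seed"]),
        demography=Demography(
            body_surface_area=float(d["body_surface_area"]),
            creatinine_clearance=float(d["creatinine_clearance"]),
            starting_age=float(d["starting_age"]),
        ),
        costs=CostTable(
            drug={k: float(v) for k, v in c["drug"].items()},
            ae={k: float(v) for k, v in c["ae"].items()},
            admin={k: float(v) for k, v in c["admin"].items()},
            terminal_care=float(c["terminal_care"]),
            bsc_per_cycle=float(c["bsc_per_cycle"]),
            follow_up_visit=float(c["follow_up_visit"]),
        ),
        utilities=UtilityTable(
            u_pfs=float(u["u_pfs"]),
            u_pd=float(u["u_pd"]),
            u_death=float(u["u_death"]),
            ae_disutility={k: float(v) for k, v in u["ae_disutility"].items()},
        ),
        arms=arms,
        life_table=life_table,
        uncertain=uncertain,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg.validate()


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Serialise a configuration; numeric fields round-trip bit-for-bit."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=False,
                          default_flow_style=None)
    Path(path).write_text(text)


def load_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = yaml.safe_load(p.read_text())
    return config_from_dict(data)
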