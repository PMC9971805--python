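import numpy as np
import pytest

from psmcea.engine import TimeGrid, state_occupancy
from psmcea.params import AE_NAMES
from psmcea.valuation import (
    RegimenSchedule,
    accumulate,
    ae_burden,
    pfs_cycle_cost,
    post_progression_cycle_cost,
)


@pytest.fixture()
def schedule(base_config):
    return RegimenSchedule.from_config(base_config)


def _trace(config, arm_id, rate=None):
    arm = config.arms[arm_id]
    return state_occupancy(
        arm.pfs_dist, arm.os_dist, TimeGrid.from_config(config),
        discount_rate=config.discount_rate if rate is None else rate,
    )


class TestAeBurden:
    def test_chemo_arm_cost_arithmetic(self, base_config):
        # independent arithmetic over the incidence and unit-cost rows
        arm = base_config.arms["chemo"]
        expected = (0.359 * 571.98 + 0.417 * 451.11
                    + 0.538 * 496.46 + 0.179 * 3820.77)
        cost, _ = ae_burden(arm, base_config.costs, base_config.utilities,
                            base_config.cycle_years)
        assert expected == pytest.approx(1344.47, abs=0.01)
        assert cost == pytest.approx(expected, rel=1e-12)

    def test_tc_arm_qaly_decrement_arithmetic(self, base_config):
        arm = base_config.arms["tc"]
        expected = (0.299 * 0.07 + 0.357 * 0.20 + 0.555 * 0.20
                    + 0.172 * 0.11) * (21.0 / 365.25)
        _, dec = ae_burden(arm, base_config.costs, base_config.utilities,
                           base_config.cycle_years)
        assert dec == pytest.approx(expected, rel=1e-12)
        assert dec == pytest.approx(0.0128, abs=2e-4)

    def test_zero_incidence_is_free(self, base_config):
        arm = base_config.copy().arms["tc"]
        arm.ae_incidence = {ae: 0.0 for ae in AE_NAMES}
        assert ae_burden(arm, base_config.costs, base_config.utilities,
                         base_config.cycle_years) == (0.0, 0.0)


class TestPfsCycleCost:
    def test_tc_nonsquamous_induction_stacks_all_drugs(self, base_config, schedule):
        costs = base_config.costs
        got = pfs_cycle_cost(1, base_config.arms["tc"], schedule, costs,
                             histology_weight_squamous=0.0)
        expected = 375.0 + 841.48 + 55.18 + costs.cycle_bundle  # cycle 1: no CT
        assert got == pytest.approx(expected, rel=1e-12)

    def test_chemo_squamous_maintenance_is_administration_only(self, base_config, schedule):
        costs = base_config.costs
        got = pfs_cycle_cost(5, base_config.arms["chemo"], schedule, costs,
                             histology_weight_squamous=1.0)
        assert got == pytest.approx(costs.cycle_bundle, rel=1e-12)

    def test_toripalimab_stops_after_two_year_cap(self, base_config, schedule):
        costs = base_config.costs
        assert schedule.toripalimab_cap_cycles == 34
        at_cap = pfs_cycle_cost(33, base_config.arms["tc"], schedule, costs, 1.0,
                                ct_interval_cycles=10**9)
        past_cap = pfs_cycle_cost(35, base_config.arms["tc"], schedule, costs, 1.0,
                                  ct_interval_cycles=10**9)
        assert at_cap - past_cap == pytest.approx(375.0, rel=1e-12)

    def test_ct_booked_on_interval(self, base_config, schedule):
        costs = base_config.costs
        with_ct = pfs_cycle_cost(4, base_config.arms["chemo"], schedule, costs, 1.0)
        without = pfs_cycle_cost(5, base_config.arms["chemo"], schedule, costs, 1.0)
        assert with_ct - without == pytest.approx(56.05, rel=1e-9)


class TestPostProgression:
    def test_tc_one_time_docetaxel_drug_component(self, base_config, schedule):
        rule = post_progression_cycle_cost(base_config.arms["tc"],
                                           base_config.costs, schedule)
        drug_only = 0.511 * 4 * 31.60
        bundle_part = 0.511 * 4 * base_config.costs.cycle_bundle
        assert drug_only == pytest.approx(64.59, abs=0.01)
        assert rule.one_time_per_progression == pytest.approx(
            drug_only + bundle_part, rel=1e-12
        )

    def test_chemo_crossover_toripalimab_per_cycle(self, base_config, schedule):
        rule = post_progression_cycle_cost(base_config.arms["chemo"],
                                           base_config.costs, schedule)
        assert rule.crossover_per_cycle == pytest.approx(0.538 * 375.0, rel=1e-12)
        assert rule.crossover_per_cycle == pytest.approx(201.75, abs=1e-9)

    def test_pure_bsc_mix(self, base_config, schedule):
        arm = base_config.copy().arms["tc"]
        arm.post_progression_mix = {
            "crossover_toripalimab": 0.0, "subsequent_chemo": 0.0, "bsc": 1.0,
        }
        rule = post_progression_cycle_cost(arm, base_config.costs, schedule)
        assert rule.per_pd_cycle == pytest.approx(122.18 + 77.01, rel=1e-12)
        assert rule.one_time_per_progression == 0.0
        assert rule.crossover_per_cycle == 0.0


class TestAccumulate:
    def test_life_expectancy_identity(self, base_config):
        """Free care, full utility, no discounting: QALYs = person-years alive."""
        cfg = base_config.copy()
        cfg.discount_rate = 0.0
        cfg.costs.drug = {k: 0.0 for k in cfg.costs.drug}
        cfg.costs.ae = {k: 0.0 for k in cfg.costs.ae}
        cfg.costs.admin = {k: 0.0 for k in cfg.costs.admin}
        cfg.costs.terminal_care = 0.0
        cfg.costs.bsc_per_cycle = 0.0
        cfg.costs.follow_up_visit = 0.0
        cfg.utilities.u_pfs = 1.0
        cfg.utilities.u_pd = 1.0
        cfg.utilities.ae_disutility = {k: 0.0 for k in cfg.utilities.ae_disutility}
        trace = _trace(cfg, "tc")
        val = accumulate(trace, cfg.arms["tc"], cfg)
        assert val.total_cost == 0.0
        person_years = np.sum(cfg.cycle_years * (1.0 - trace.p_dead))
        assert val.qalys == pytest.approx(person_years, rel=1e-12)
        assert val.life_years == pytest.approx(person_years, rel=1e-12)

    def test_components_add_to_total(self, base_config):
        trace = _trace(base_config, "chemo")
        val = accumulate(trace, base_config.arms["chemo"], base_config)
        assert val.total_cost == pytest.approx(sum(val.components.values()), abs=1e-6)
        assert set(val.components) == {
            "drug", "administration", "adverse_events", "post_progression",
            "follow_up", "terminal_care",
        }

    def test_unit_cost_monotonicity(self, base_config):
        trace = _trace(base_config, "tc")
        base = accumulate(trace, base_config.arms["tc"], base_config).total_cost
        dearer = base_config.copy()
        dearer.set_param("costs.drug.pemetrexed", 1000.0)
        assert accumulate(trace, dearer.arms["tc"], dearer).total_cost > base

    def test_pfs_utility_monotonicity(self, base_config):
        trace = _trace(base_config, "tc")
        base = accumulate(trace, base_config.arms["tc"], base_config).qalys
        better = base_config.copy()
        better.utilities.u_pfs = 0.95
        assert accumulate(trace, better.arms["tc"], better).qalys > base

    def test_zero_discount_reproduces_undiscounted_mirrors(self, base_config):
        cfg = base_config.copy()
        cfg.discount_rate = 0.0
        trace = _trace(cfg, "chemo")
        val = accumulate(trace, cfg.arms["chemo"], cfg)
        assert val.total_cost == pytest.approx(val.total_cost_undiscounted, rel=1e-12)
        assert val.qalys == pytest.approx(val.qalys_undiscounted, rel=1e-12)

    def test_discounted_at_most_undiscounted(self, base_config):
        trace = _trace(base_config, "tc")
        val = accumulate(trace, base_config.arms["tc"], base_config)
        assert val.total_cost < val.total_cost_undiscounted
        assert val.qalys < val.qalys_undiscounted

    def test_terminal_care_booking(self, base_config):
        trace = _trace(base_config, "tc")
        val = accumulate(trace, base_config.arms["tc"], base_config)
        expected = 2241.18 * np.sum(trace.discount * trace.new_deaths)
        assert val.components["terminal_care"] == pytest.approx(expected, rel=1e-12)
        assert val.components["terminal_care"] <= 2241.18

    def test_grid_mismatch_rejected(self, base_config):
        arm = base_config.arms["tc"]
        short = state_occupancy(arm.pfs_dist, arm.os_dist, TimeGrid(21.0, 50))
        with pytest.raises(ValueError, match="grid"):
            accumulate(short, arm, base_config)
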