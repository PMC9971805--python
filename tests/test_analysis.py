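import math

import numpy as np
import pytest

import psmcea as m
from psmcea.analysis import (
    CeacCurve,
    _moment_matched_sampler,
    ceac,
    ceac_crossing,
    icer,
    owsa,
    psa,
    run_base_case,
    run_subgroup,
)
from psmcea.params import UncertainParam


class TestIcer:
    def test_published_increments_reproduce_ratio(self):
        value, flag = icer(11777.0, 0.54)
        assert value == pytest.approx(11777.0 / 0.54, rel=1e-12)
        assert value == pytest.approx(21809.26, abs=0.01)
        assert flag == "none"

    def test_free_gain_costs_nothing_per_qaly(self):
        assert icer(0.0, 0.5) == (0.0, "none")

    def test_dominance_sign_rules(self):
        assert icer(-100.0, 0.5)[1] == "intervention_dominant"
        assert icer(100.0, -0.5)[1] == "intervention_dominated"

    def test_zero_effect_is_undefined_not_division(self):
        value, flag = icer(100.0, 0.0)
        assert math.isnan(value) and flag == "undefined"
        assert icer(0.0, 0.0) == (0.0, "equivalent")


class TestBaseCase:
    def test_deterministic_and_reproducible(self, base_config, base_result):
        again = run_base_case(base_config)
        assert again.delta_cost == base_result.delta_cost
        assert again.delta_qalys == base_result.delta_qalys
        assert again.icer == base_result.icer

    def test_identical_arms_are_equivalent(self, base_config):
        cfg = base_config.copy()
        cfg.arms["tc"] = cfg.arms["chemo"]
        import dataclasses
        cfg.arms["tc"] = dataclasses.replace(cfg.arms["chemo"], arm_id="tc")
        result = run_base_case(cfg)
        assert result.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert result.delta_qalys == pytest.approx(0.0, abs=1e-12)
        assert result.dominance == "equivalent"

    def test_undiscounted_qalys_exceed_discounted(self, base_config, base_result):
        cfg = base_config.copy()
        cfg.discount_rate = 0.0
        undiscounted = run_base_case(cfg)
        assert undiscounted.intervention.qalys > base_result.intervention.qalys
        assert undiscounted.comparator.qalys > base_result.comparator.qalys

    def test_icer_consistent_with_increments(self, base_result):
        assert base_result.icer == pytest.approx(
            base_result.delta_cost / base_result.delta_qalys, rel=1e-12
        )


class TestOwsa:
    def test_degenerate_range_has_zero_span(self, base_config):
        rule = UncertainParam("pinned pemetrexed", "costs.drug.pemetrexed",
                              "gamma", 841.48, 841.48)
        rows = owsa(base_config, [rule])
        assert rows[0].span == pytest.approx(0.0, abs=1e-9)

    def test_collapsed_ranges_reproduce_base_icer(self, base_config, base_result):
        rules = [
            UncertainParam(r.name, r.path, r.family,
                           base_config.get_param(r.path),
                           base_config.get_param(r.path))
            for r in base_config.uncertain[:6]
        ]
        for row in owsa(base_config, rules):
            assert row.icer_low == pytest.approx(base_result.icer, rel=1e-12)
            assert row.icer_high == pytest.approx(base_result.icer, rel=1e-12)

    def test_pfs_utility_direction(self, base_config):
        # more valuable PFS time -> larger QALY gain -> smaller ICER
        rule = UncertainParam("u_pfs", "utilities.u_pfs", "beta", 0.64, 0.96)
        row = owsa(base_config, [rule])[0]
        assert row.icer_low > row.icer_high

    def test_rows_sorted_by_span(self, base_config):
        rows = owsa(base_config, base_config.uncertain[:8])
        spans = [r.span for r in rows]
        assert spans == sorted(spans, reverse=True)

    def test_base_case_restored_between_parameters(self, base_config, base_result):
        owsa(base_config, base_config.uncertain[:4])
        assert run_base_case(base_config).icer == base_result.icer


class TestMomentMatching:
    def test_gamma_pemetrexed_hyperparameters(self):
        # sd = (1009.78 - 673.18) / 3.92 ~ 85.87; shape = mean^2/var, scale = var/mean
        rule = UncertainParam("pem", "costs.drug.pemetrexed", "gamma", 673.18, 1009.78)
        rng = np.random.default_rng(0)
        draws = np.array([_moment_matched_sampler(rule, 841.48)(rng)
                          for _ in range(20000)])
        sd = (1009.78 - 673.18) / (2 * 1.959963984540054)
        assert sd == pytest.approx(85.87, abs=0.01)
        assert draws.mean() == pytest.approx(841.48, abs=4 * sd / math.sqrt(20000))
        assert draws.std() == pytest.approx(sd, rel=0.05)

    def test_beta_pfs_utility_hyperparameters(self):
        rule = UncertainParam("u_pfs", "utilities.u_pfs", "beta", 0.64, 0.96)
        rng = np.random.default_rng(1)
        draws = np.array([_moment_matched_sampler(rule, 0.80)(rng)
                          for _ in range(20000)])
        sd = 0.32 / (2 * 1.959963984540054)
        assert draws.mean() == pytest.approx(0.80, abs=4 * sd / math.sqrt(20000))
        assert draws.std() == pytest.approx(sd, rel=0.05)
        assert np.all((draws > 0) & (draws < 1))

    def test_fixed_and_degenerate_rules_not_sampled(self):
        fixed = UncertainParam("tori", "costs.drug.toripalimab", "fixed", 300.0, 375.0)
        degenerate = UncertainParam("x", "costs.drug.docetaxel", "gamma", 31.6, 31.6)
        assert _moment_matched_sampler(fixed, 375.0) is None
        assert _moment_matched_sampler(degenerate, 31.6) is None


class TestPsa:
    def test_reproducible_given_seed(self, base_config):
        a = psa(base_config, n_draws=20, seed=123)
        b = psa(base_config, n_draws=20, seed=123)
        assert [s.values for s in a] == [s.values for s in b]
        assert [s.result.icer for s in a] == [s.result.icer for s in b]

    def test_fixed_parameters_never_vary(self, psa_samples):
        for s in psa_samples[:50]:
            assert "costs.drug.toripalimab" not in s.values
            assert "discount_rate" not in s.values

    def test_sample_means_converge_to_point_estimates(self, base_config, psa_samples):
        n = len(psa_samples)
        checked = 0
        for rule in base_config.uncertain:
            if rule.family == "fixed" or rule.low == rule.high:
                continue
            point = base_config.get_param(rule.path)
            sd = (rule.high - rule.low) / (2 * 1.959963984540054)
            draws = np.array([s.values[rule.path] for s in psa_samples])
            tol = 4 * sd / math.sqrt(n)
            if rule.path == "utilities.ae_disutility.leukopenia":
                continue  # printed range does not bracket the point estimate
            assert draws.mean() == pytest.approx(point, abs=tol), rule.name
            checked += 1
        assert checked > 30

    def test_all_draws_in_first_quadrant(self, psa_samples):
        dc = np.array([s.result.delta_cost for s in psa_samples])
        de = np.array([s.result.delta_qalys for s in psa_samples])
        assert np.all(dc > 0) and np.all(de > 0)


class TestCeac:
    def test_zero_wtp_with_positive_costs(self, psa_samples):
        curve = ceac(psa_samples, wtp_grid=[0.0])
        assert curve.acceptance[0] == 0.0

    def test_monotone_when_all_gains_positive(self, psa_samples):
        curve = ceac(psa_samples)
        assert np.all(np.diff(curve.acceptance) >= 0)

    def test_saturates_at_high_wtp(self, psa_samples):
        curve = ceac(psa_samples, wtp_grid=[1e9])
        assert curve.acceptance[0] == 1.0

    def test_crossing_interpolates(self):
        curve = CeacCurve(np.array([0.0, 100.0, 200.0]),
                          np.array([0.0, 0.25, 0.75]))
        # linear interpolation between (100, 0.25) and (200, 0.75)
        assert ceac_crossing(curve, 0.5) == pytest.approx(150.0)

    def test_flat_curves(self):
        always = CeacCurve(np.array([0.0, 100.0]), np.array([1.0, 1.0]))
        never = CeacCurve(np.array([0.0, 100.0]), np.array([0.0, 0.0]))
        assert ceac_crossing(always) == 0.0
        assert ceac_crossing(never) is None

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac([])


class TestSubgroup:
    def _subgroup_config(self, base_config):
        """A user-style subgroup configuration with synthetic survival
        parameters (the published subgroup estimates are not shipped)."""
        cfg = base_config.copy()
        cfg.arms["tc"].pfs_dist = m.DistSpec("lognormal", (2.45, 0.9))
        cfg.arms["tc"].os_dist = m.DistSpec("loglogistic", (1.6, 28.0))
        cfg.arms["chemo"].pfs_dist = m.DistSpec("loglogistic", (2.4, 6.5))
        cfg.arms["chemo"].os_dist = m.DistSpec("lognormal", (2.95, 0.8))
        return cfg

    def test_squamous_run_contains_no_pemetrexed_cost(self, base_config):
        cfg = self._subgroup_config(base_config)
        result = run_subgroup(cfg, "squamous")
        pricier = cfg.copy()
        pricier.set_param("costs.drug.pemetrexed", 10 * 841.48)
        # pemetrexed price is structurally absent from the squamous regimen
        assert run_subgroup(pricier, "squamous").delta_cost == pytest.approx(
            result.delta_cost, rel=1e-12
        )
        assert run_subgroup(pricier, "non_squamous").delta_cost != pytest.approx(
            result.delta_cost, rel=1e-6
        )

    def test_identical_arm_subgroup_has_zero_gain(self, base_config):
        import dataclasses
        cfg = self._subgroup_config(base_config)
        cfg.arms["tc"] = dataclasses.replace(
            cfg.arms["chemo"], arm_id="tc", on_immunotherapy=False
        )
        result = run_subgroup(cfg, "squamous")
        assert result.delta_qalys == pytest.approx(0.0, abs=1e-12)

    def test_icer_definition_holds(self, base_config):
        result = run_subgroup(self._subgroup_config(base_config), "non_squamous")
        assert result.icer == pytest.approx(
            result.delta_cost / result.delta_qalys, rel=1e-12
        )

    def test_invalid_histology_rejected(self, base_config):
        with pytest.raises(ValueError, match="histology"):
            run_subgroup(base_config, "large_cell")
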