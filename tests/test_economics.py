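"""Cost/utility accrual, incremental statistics, PAP and price scenarios."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lungcea.economics import (AEProfile, ArmSpec, CEResult, CostInputs,
                               PAP_PAID_DEFAULT, UtilityInputs, accrue,
                               apply_pap, apply_price_fraction, compare)
from lungcea.markov import ModelSettings, run_cohort
from lungcea.survival import SurvivalModel

FLAT = SurvivalModel("exponential", (1e-15,))
COSTS = CostInputs()
UTILS = UtilityInputs()


def one_cycle_settings() -> ModelSettings:
    # a single 3-week cycle, no discounting, no background mortality
    return ModelSettings(horizon_years=21 / 365.25, annual_discount_rate=0.0,
                         natural_mortality_annual=0.0)


class TestAccrue:
    def test_single_cycle_all_pfs_costs_drug_plus_followup(self):
        s = one_cycle_settings()
        trace = run_cohort(FLAT, FLAT, s)
        arm = ArmSpec("atezolizumab", FLAT, FLAT,
                      drug_cost_per_cycle=COSTS.atezolizumab_per_cycle,
                      treatment_cycles=1, ae_profile=AEProfile.none())
        res = accrue(trace, arm, COSTS, UTILS, s)
        assert res.cost == pytest.approx(4218.61 + 76.05, abs=1e-6)

    def test_all_dead_trace_incurs_terminal_care_only(self):
        s = one_cycle_settings()
        trace = pd.DataFrame({
            "cycle": [0, 1], "t_months": [0.0, s.cycle_months],
            "n_pfs": [1.0, 0.0], "n_pd": [0.0, 0.0],
            "n_death": [0.0, 1.0], "new_deaths": [0.0, 1.0],
        })
        arm = ArmSpec("bsc", FLAT, FLAT, treatment_cycles=1,
                      ae_profile=AEProfile.none())
        res = accrue(trace, arm, COSTS, UTILS, s)
        assert res.cost == pytest.approx(COSTS.terminal_care_once)
        assert res.qaly == pytest.approx(0.0)

    def test_unit_utilities_make_qalys_equal_life_years(self, config):
        gs = config.survival["pdl1"]
        trace = run_cohort(gs.atezolizumab_pfs, gs.atezolizumab_os, config.settings)
        arm = ArmSpec("atezolizumab", gs.atezolizumab_pfs, gs.atezolizumab_os,
                      ae_profile=AEProfile.none())
        utils = UtilityInputs(u_pfs=1.0, u_pd=1.0 - 1e-12, disutility_pyrexia=0.0)
        res = accrue(trace, arm, COSTS, utils, config.settings)
        assert res.qaly == pytest.approx(res.ly, rel=1e-9)

    def test_discounted_totals_never_exceed_undiscounted(self, config):
        from lungcea.analysis import build_arms
        for group in config.survival:
            arm, _ = build_arms(config, group)
            trace = run_cohort(arm.pfs_model, arm.os_model, config.settings)
            res = accrue(trace, arm, COSTS, UTILS, config.settings)
            assert res.cost <= res.cost_undiscounted
            assert res.ly <= res.ly_undiscounted
            assert res.qaly <= res.qaly_undiscounted
            assert res.qaly <= res.ly

    def test_schedule_longer_than_horizon_rejected(self):
        s = one_cycle_settings()
        trace = run_cohort(FLAT, FLAT, s)
        arm = ArmSpec("atezolizumab", FLAT, FLAT, treatment_cycles=16)
        with pytest.raises(ValueError):
            accrue(trace, arm, COSTS, UTILS, s)

    def test_identical_arms_differ_only_through_disutility(self, config):
        gs = config.survival["pdl1"]
        s = config.settings
        trace = run_cohort(gs.atezolizumab_pfs, gs.atezolizumab_os, s)
        treated = ArmSpec("atezolizumab", gs.atezolizumab_pfs, gs.atezolizumab_os,
                          ae_profile=AEProfile())
        untreated = ArmSpec("bsc", gs.atezolizumab_pfs, gs.atezolizumab_os,
                            ae_profile=AEProfile.none())
        res_t = accrue(trace, treated, COSTS, UTILS, s)
        res_u = accrue(trace, untreated, COSTS, UTILS, s)
        assert res_t.ly == pytest.approx(res_u.ly, abs=1e-12)
        expected_dq = AEProfile().pyrexia * UTILS.disutility_pyrexia * s.cycle_years
        assert res_u.qaly - res_t.qaly == pytest.approx(expected_dq, rel=1e-9)


class TestCompare:
    def _res(self, cost, qaly, ly=6.0):
        return CEResult("x", cost, ly, qaly, cost, ly, qaly)

    @pytest.mark.parametrize("dc,dq,expected_icer", [
        (48_971.42, 0.45, 108_825.37),    # published base-case incrementals
        (16_482.42, 0.45, 36_627.60),     # published PAP incrementals
        (41_141.53, 0.04, 1_028_538.22),  # all-randomised incrementals
    ])
    def test_published_icer_identities(self, dc, dq, expected_icer):
        cmp_ = compare(self._res(100_000 + dc, 3.0 + dq), self._res(100_000, 3.0),
                       wtp=27_354.0)
        assert cmp_.icer == pytest.approx(expected_icer, rel=1e-3)
        assert cmp_.icer * cmp_.delta_qaly == pytest.approx(cmp_.delta_cost, rel=1e-12)

    def test_negative_icer_classified_dominated(self):
        cmp_ = compare(self._res(141_370.0, 3.562), self._res(100_000.0, 3.565),
                       wtp=27_354.0)
        assert cmp_.classification == "dominated"
        assert cmp_.icer < 0

    def test_zero_delta_qaly_sentinel(self):
        cmp_ = compare(self._res(105_000.0, 3.5), self._res(100_000.0, 3.5),
                       wtp=27_354.0)
        assert math.isnan(cmp_.icer)
        assert cmp_.classification == "not cost-effective"

    def test_nmb_definition(self):
        cmp_ = compare(self._res(150_000.0, 4.0), self._res(100_000.0, 3.5),
                       wtp=30_000.0)
        assert cmp_.nmb == pytest.approx(30_000.0 * 0.5 - 50_000.0)

    def test_cheaper_and_better_is_dominant(self):
        cmp_ = compare(self._res(90_000.0, 4.0), self._res(100_000.0, 3.5),
                       wtp=27_354.0)
        assert cmp_.classification == "dominant"


class TestScenarios:
    def test_pay_all_schedule_is_identity(self, config):
        from lungcea.analysis import build_arms, run_group
        arm, _ = build_arms(config, "pdl1")
        assert apply_pap(arm, frozenset(range(1, 17))) == arm

    def test_default_pap_zeroes_about_eight_cycles_of_drug_spend(self, config):
        """Discounted drug spend falls by just under eight cycle-costs
        (eight free cycles weighted by PFS occupancy and discounting)."""
        from lungcea.analysis import build_arms
        arm, _ = build_arms(config, "pdl1")
        s = config.settings
        trace = run_cohort(arm.pfs_model, arm.os_model, s)
        base = accrue(trace, arm, config.costs, config.utilities, s)
        pap = accrue(trace, apply_pap(arm, config.pap_paid_cycles),
                     config.costs, config.utilities, s)
        saved_cycles = (base.breakdown["drug"] - pap.breakdown["drug"]) / 4218.61
        # oracle: eight free cycles, each weighted by start-of-cycle PFS
        # occupancy and the discount factor
        trace_pfs = trace["n_pfs"].to_numpy()[:-1]
        dfs = s.discount_factors(len(trace_pfs))
        expected = sum(trace_pfs[k - 1] * dfs[k - 1] for k in range(9, 17))
        assert saved_cycles == pytest.approx(expected, rel=1e-9)
        assert 6.5 <= saved_cycles <= 8.0
        assert pap.breakdown["drug"] < base.breakdown["drug"]

    def test_free_all_schedule_eliminates_drug_cost(self, config):
        from lungcea.analysis import build_arms
        arm, _ = build_arms(config, "pdl1")
        s = config.settings
        trace = run_cohort(arm.pfs_model, arm.os_model, s)
        free = accrue(trace, apply_pap(arm, frozenset()),
                      config.costs, config.utilities, s)
        assert free.breakdown["drug"] == 0.0

    def test_price_fraction_identity_and_arithmetic(self, config):
        from lungcea.analysis import build_arms
        arm, _ = build_arms(config, "pdl1")
        assert apply_price_fraction(arm, 1.0) == arm
        half = apply_price_fraction(arm, 0.5)
        assert half.drug_cost_per_cycle * half.price_multiplier == pytest.approx(2109.305)
        with pytest.raises(ValueError):
            apply_price_fraction(arm, 0.0)

    def test_icer_decreases_with_deeper_price_cuts(self, config):
        """Along the 0.3-1.0 price grid the ICER is strictly increasing in the
        retained price fraction (QALYs are unaffected by price)."""
        from lungcea.analysis import run_group
        icers = [run_group(config, "pdl1", f"price_{f:g}")[2].icer
                 for f in (0.3, 0.5, 0.7, 1.0)]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_price_cut_and_pap_never_raise_total_cost(self, config):
        from lungcea.analysis import run_group
        base_cost = run_group(config, "pdl1")[0].cost
        for scenario in ("pap", "price_0.7", "price_0.3"):
            assert run_group(config, "pdl1", scenario)[0].cost <= base_cost
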