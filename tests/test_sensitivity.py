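"""Five-scenario sensitivity analysis."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rossercea import (
    TrialConfig,
    classify_record,
    generate_trial,
    run_scenarios,
    scenario1_individual,
    scenario2_subgroup_mean,
    scenario3_condition_mean,
    scenario4_frozen_control,
    scenario5_pretest_extrapolation,
)
from rossercea._rounding import round_half_up
from rossercea.scales import DEFAULT_SCHEME, Disability


class TestScenario1:
    def test_reference_between_group_gain(self, ref_records):
        """From the published state counts: intervention +0.0048, control
        -0.0135 (what the printed counts imply), between 0.018."""
        res = scenario1_individual(ref_records)
        assert round_half_up(res.dh_intervention, 4) == 0.0048
        assert round_half_up(res.dh_control, 4) == -0.0135
        assert round_half_up(res.dh_between, 3) == 0.018

    def test_identical_pre_post_records_give_zeros(self, ref_records):
        from dataclasses import replace

        frozen = [
            replace(r, cesd_post=r.cesd_pre, k10_post=r.k10_pre) for r in ref_records
        ]
        res = scenario1_individual(frozen)
        assert res.dh_intervention == 0.0
        assert res.dh_control == 0.0

    def test_equals_per_participant_oracle_on_synthetic_data(self, valuation):
        records = generate_trial(TrialConfig(seed=5))
        res = scenario1_individual(records, valuation)
        for arm, got in (
            ("intervention", res.dh_intervention),
            ("control", res.dh_control),
        ):
            completers = [r for r in records if r.arm == arm and r.completer]
            oracle = math.fsum(
                valuation[classify_record(r, "post")] - valuation[classify_record(r, "pre")]
                for r in completers
            ) / len(completers)
            assert got == pytest.approx(oracle, abs=1e-12)


class TestScenario2:
    def test_published_subgroup_means_reproduce(self):
        res = scenario2_subgroup_mean()
        assert round_half_up(res.dh_intervention, 3) == 0.008
        assert round_half_up(res.dh_control, 3) == -0.004
        assert round_half_up(res.dh_between, 3) == 0.012

    def test_identical_arms_give_zero_between(self):
        summaries = {
            arm: {
                "subclinical": {"pre": (10.0, 22.0, 10), "post": (10.0, 22.0, 10)},
                "mild_moderate": {"pre": (19.0, 24.0, 5), "post": (19.0, 24.0, 5)},
                "moderate_severe": {"pre": (30.0, 31.0, 5), "post": (30.0, 31.0, 5)},
            }
            for arm in ("intervention", "control")
        }
        res = scenario2_subgroup_mean(summaries)
        assert res.dh_between == 0.0

    def test_inconsistent_subgroup_sizes_rejected(self):
        summaries = {
            "intervention": {
                "subclinical": {"pre": (10.0, 22.0, 10), "post": (10.0, 22.0, 11)},
            },
            "control": {
                "subclinical": {"pre": (10.0, 22.0, 10), "post": (10.0, 22.0, 10)},
            },
        }
        with pytest.raises(ValueError, match="subgroup sizes"):
            scenario2_subgroup_mean(summaries)


class TestScenario3:
    def test_published_arm_means_reproduce(self):
        res = scenario3_condition_mean()
        assert round_half_up(res.dh_intervention, 3) == 0.020
        assert round_half_up(res.dh_control, 3) == -0.020
        assert round_half_up(res.dh_between, 3) == 0.040

    def test_no_change_gives_zero(self):
        means = {
            arm: {"cesd_pre": 22.6, "cesd_post": 22.6, "k10": 33.2}
            for arm in ("intervention", "control")
        }
        res = scenario3_condition_mean(means)
        assert res.dh_between == 0.0

    def test_exact_half_step_option(self):
        res = scenario3_condition_mean(exact_half_step=True)
        # unrounded C->D half-gap at disability II: (0.973 - 0.932)/2
        assert res.dh_intervention == pytest.approx(0.0205)

    def test_state_change_uses_weight_difference(self):
        means = {
            "intervention": {"cesd_pre": 22.6, "cesd_post": 10.0, "k10": 33.2},
            "control": {"cesd_pre": 22.6, "cesd_post": 22.6, "k10": 33.2},
        }
        res = scenario3_condition_mean(means)
        # II-D (0.932) -> I-D (0.967)
        assert res.dh_intervention == pytest.approx(0.967 - 0.932)


class TestScenario4:
    def test_control_frozen_and_between_equals_intervention(self, ref_records):
        s1 = scenario1_individual(ref_records)
        s4 = scenario4_frozen_control(ref_records)
        assert s4.dh_control == 0.0
        assert s4.dh_between == s1.dh_intervention
        assert round_half_up(s4.dh_between, 3) == 0.005


class TestScenario5:
    def test_unit_factors_give_zeros(self, ref_records):
        res = scenario5_pretest_extrapolation(
            ref_records, factors={"intervention": 1.0, "control": 1.0}
        )
        assert res.dh_intervention == 0.0 and res.dh_control == 0.0

    def test_single_record_reclassification(self, valuation):
        from rossercea import ParticipantRecord

        # CES-D 32 (disability III) halves to 16 (disability II)
        r = [
            ParticipantRecord(id="a", arm="intervention", cesd_pre=32, k10_pre=22,
                              cesd_post=30, k10_post=22, completer=True),
            ParticipantRecord(id="b", arm="control", cesd_pre=32, k10_pre=22,
                              cesd_post=30, k10_post=22, completer=True),
        ]
        res = scenario5_pretest_extrapolation(r, factors={"intervention": 2.0, "control": 1.0})
        assert DEFAULT_SCHEME.cesd_to_disability(32 / 2.0) is Disability.II
        w = valuation
        from rossercea import Distress, HealthState

        expected = w[HealthState(Disability.II, Distress.B)] - w[HealthState(Disability.III, Distress.B)]
        assert res.dh_intervention == pytest.approx(expected)

    def test_published_factors_give_smaller_positive_between_gain(self, ref_records):
        s1 = scenario1_individual(ref_records)
        s5 = scenario5_pretest_extrapolation(ref_records)
        assert 0 < s5.dh_between < s1.dh_between

    def test_nonpositive_factor_rejected(self, ref_records):
        with pytest.raises(ValueError, match="positive"):
            scenario5_pretest_extrapolation(
                ref_records, factors={"intervention": 0.0, "control": 1.0}
            )


class TestRunScenarios:
    def test_between_identity_holds_for_every_scenario(self, ref_records):
        for res in run_scenarios(ref_records):
            assert res.dh_between == res.dh_intervention - res.dh_control

    def test_unknown_scenario_rejected(self, ref_records):
        with pytest.raises(ValueError, match="scenario id"):
            run_scenarios(ref_records, scenarios=[6])


@given(seed=st.integers(0, 2**16))
@settings(deadline=None, max_examples=10)
def test_between_identity_on_synthetic_trials(seed):
    records = generate_trial(TrialConfig(seed=seed))
    for res in run_scenarios(records, scenarios=(1, 4, 5)):
        assert res.dh_between == pytest.approx(res.dh_intervention - res.dh_control, abs=1e-15)
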