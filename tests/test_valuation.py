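"""Valuation: descriptive matrices, QOL totals, ΔH, published reproduction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rossercea import (
    DeltaH,
    DescriptiveMatrix,
    Disability,
    Distress,
    GroupQol,
    HealthState,
    ParticipantRecord,
    ValuationMatrix,
    between_groups_delta_h,
    build_descriptive_matrix,
    classify_record,
    delta_h,
    total_qol,
)
from rossercea._rounding import round_half_up


class TestValuationMatrix:
    @pytest.mark.parametrize(
        "state, weight",
        [
            (HealthState(Disability.I, Distress.A), 1.000),
            (HealthState(Disability.II, Distress.D), 0.932),
            (HealthState(Disability.III, Distress.C), 0.956),
            (HealthState(Disability.V, Distress.D), 0.700),
            (HealthState(Disability.VI, Distress.D), 0.000),
        ],
    )
    def test_packaged_weights(self, valuation, state, weight):
        assert valuation[state] == weight

    def test_missing_cell_listed(self, valuation):
        weights = dict(valuation.weights)
        del weights[HealthState(Disability.III, Distress.B)]
        with pytest.raises(ValueError, match="IIIB"):
            ValuationMatrix(weights)

    def test_monotonicity_violation_rejected(self, valuation):
        weights = dict(valuation.weights)
        weights[HealthState(Disability.II, Distress.C)] = 0.999  # > (II, B)
        with pytest.raises(ValueError, match="II"):
            ValuationMatrix(weights)

    def test_weight_out_of_unit_interval_rejected(self, valuation):
        weights = dict(valuation.weights)
        weights[HealthState(Disability.IV, Distress.B)] = 1.2
        with pytest.raises(ValueError, match="outside"):
            ValuationMatrix(weights)


class TestDescriptiveMatrix:
    def test_counts_from_reference_records_match_published(self, ref_records, ref_matrices):
        for (arm, tp), published in ref_matrices.items():
            rebuilt = build_descriptive_matrix(ref_records, arm, tp)
            assert dict(rebuilt.counts) == dict(published.counts)
            assert rebuilt.n == published.n

    def test_single_record(self):
        r = ParticipantRecord(
            id="a", arm="control", cesd_pre=0, k10_pre=10,
            cesd_post=0, k10_post=10, completer=True,
        )
        m = build_descriptive_matrix([r], "control", "pre")
        assert dict(m.counts) == {HealthState(Disability.I, Distress.A): 1}
        assert m.n == 1

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError, match="no completer"):
            build_descriptive_matrix([], "control", "pre")

    def test_grid_layout(self, ref_matrices):
        frame = ref_matrices[("intervention", "pre")].to_frame()
        assert frame.loc["I", "B"] == 8
        assert frame.values.sum() == 43


class TestTotalQol:
    # published totals; control posttest computes 56.06 from the printed
    # counts (the printed 55.96 is a probable table misprint)
    @pytest.mark.parametrize(
        "arm, tp, expected",
        [
            ("intervention", "pre", 40.82),
            ("intervention", "post", 41.02),
            ("control", "pre", 56.86),
            ("control", "post", 56.06),
        ],
    )
    def test_published_totals(self, ref_matrices, valuation, arm, tp, expected):
        q = total_qol(ref_matrices[(arm, tp)], valuation)
        assert round_half_up(q.total, 2) == expected

    def test_perfect_health_totals_n(self, valuation):
        m = DescriptiveMatrix(
            counts={HealthState(Disability.I, Distress.A): 7}, arm="control", timepoint="pre"
        )
        q = total_qol(m, valuation)
        assert q.total == 7.0 and q.mean == 1.0

    def test_equals_per_participant_brute_force(self, ref_records, valuation):
        """Oracle: iterate records, look up each weight, sum."""
        for arm in ("intervention", "control"):
            for tp in ("pre", "post"):
                expected = math.fsum(
                    valuation[classify_record(r, tp)]
                    for r in ref_records
                    if r.arm == arm and r.completer
                )
                q = total_qol(build_descriptive_matrix(ref_records, arm, tp), valuation)
                assert q.total == pytest.approx(expected, abs=1e-12)


class TestDeltaH:
    def test_intervention_within_group(self, ref_matrices, valuation):
        pre = total_qol(ref_matrices[("intervention", "pre")], valuation)
        post = total_qol(ref_matrices[("intervention", "post")], valuation)
        dh = delta_h(pre, post)
        assert round_half_up(dh.value, 4) == 0.0048

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="completer set"):
            delta_h(GroupQol(total=10, n=10), GroupQol(total=11, n=11))

    def test_identical_pre_post_is_zero(self, ref_matrices, valuation):
        q = total_qol(ref_matrices[("control", "pre")], valuation)
        assert delta_h(q, q).value == 0.0

    def test_maximal_single_person_gain(self, valuation):
        worst = DescriptiveMatrix(
            counts={HealthState(Disability.VI, Distress.D): 1}, arm="control", timepoint="pre"
        )
        best = DescriptiveMatrix(
            counts={HealthState(Disability.I, Distress.A): 1}, arm="control", timepoint="post"
        )
        dh = delta_h(total_qol(worst, valuation), total_qol(best, valuation))
        assert dh.value == 1.0

    @pytest.mark.parametrize(
        "intervention, control, expected",
        [(0.005, -0.015, 0.020), (0.3, 0.3, 0.0), (0.0054, -0.013, 0.0184)],
    )
    def test_between_groups_contrast(self, intervention, control, expected):
        out = between_groups_delta_h(DeltaH(intervention), DeltaH(control))
        assert out.value == pytest.approx(expected)
        assert out.scope == "between_groups"

    def test_between_groups_requires_within_group_inputs(self):
        with pytest.raises(ValueError, match="within_group"):
            between_groups_delta_h(DeltaH(0.1, scope="between_groups"), DeltaH(0.0))


_state = st.builds(
    HealthState, st.sampled_from(list(Disability)), st.sampled_from(list(Distress))
)
_counts = st.dictionaries(_state, st.integers(0, 30), min_size=1).filter(
    lambda d: sum(d.values()) >= 1
)


@given(counts=_counts)
@settings(deadline=None)
def test_counts_conservation_and_mean_bounds(counts, valuation):
    m = DescriptiveMatrix(counts=counts, arm="control", timepoint="pre")
    assert m.n == sum(counts.values())
    q = total_qol(m, valuation)
    assert 0.0 <= q.mean <= 1.0
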