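"""Deterministic sensitivity analysis: five variants of the ΔH computation.

The scenarios vary how coarsely scores are mapped into health states and
what is assumed about the control group:

1. per-participant classification (the main analysis);
2. one state per CES-D severity subgroup, from subgroup means;
3. one state per arm, from whole-arm means, with a half-step utility
   adjustment when the state does not move between timepoints;
4. the main analysis with the control group frozen (no change);
5. 12-month prediction applied directly to each participant's pretest
   score through per-arm change factors.

Every scenario reports within-arm ΔH, the between-arm contrast (always
``intervention - control`` exactly) and its 12-month extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._rounding import round_half_up
from .extrapolation import change_factor, extrapolate_delta_h
from .reference import (
    ARM_MEANS,
    REFERENCE_OUTCOMES,
    SCENARIO5_FACTORS,
    SUBGROUP_SUMMARIES,
)
from .scales import (
    CategoryScheme,
    DEFAULT_SCHEME,
    Disability,
    Distress,
    DistressSource,
    HealthState,
    ParticipantRecord,
)
from .valuation import (
    DeltaH,
    ValuationMatrix,
    build_descriptive_matrix,
    default_valuation_matrix,
    delta_h,
    total_qol,
)

__all__ = [
    "ScenarioResult",
    "scenario1_individual",
    "scenario2_subgroup_mean",
    "scenario3_condition_mean",
    "scenario4_frozen_control",
    "scenario5_pretest_extrapolation",
    "run_scenarios",
    "scenarios_frame",
]

_ARMS = ("intervention", "control")


@dataclass(frozen=True)
class ScenarioResult:
    """Within- and between-arm utility gains for one scenario."""

    scenario: int
    description: str
    dh_intervention: float
    dh_control: float
    dh_intervention_ext: float
    dh_control_ext: float

    @property
    def dh_between(self) -> float:
        return self.dh_intervention - self.dh_control

    @property
    def dh_between_extrapolated(self) -> float:
        return self.dh_intervention_ext - self.dh_control_ext


def _factors(reference: Optional[Mapping[str, object]] = None) -> dict[str, float]:
    ref = reference or REFERENCE_OUTCOMES
    return {arm: change_factor(ref[arm]) for arm in _ARMS}


def _result(
    scenario: int,
    description: str,
    dh_int: float,
    dh_ctl: float,
    factors: dict[str, float],
    already_extrapolated: bool = False,
) -> ScenarioResult:
    if already_extrapolated:
        ext_int, ext_ctl = dh_int, dh_ctl
    else:
        ext_int = extrapolate_delta_h(DeltaH(dh_int), factors["intervention"]).value
        ext_ctl = extrapolate_delta_h(DeltaH(dh_ctl), factors["control"]).value
    return ScenarioResult(
        scenario=scenario,
        description=description,
        dh_intervention=dh_int,
        dh_control=dh_ctl,
        dh_intervention_ext=ext_int,
        dh_control_ext=ext_ctl,
    )


def _arm_delta_h(
    records: Sequence[ParticipantRecord],
    arm: str,
    valuation: ValuationMatrix,
    scheme: CategoryScheme,
    distress_source: DistressSource,
) -> float:
    pre = total_qol(build_descriptive_matrix(records, arm, "pre", scheme, distress_source), valuation)
    post = total_qol(build_descriptive_matrix(records, arm, "post", scheme, distress_source), valuation)
    return delta_h(pre, post).value


def scenario1_individual(
    records: Sequence[ParticipantRecord],
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT,
    reference: Optional[Mapping[str, object]] = None,
) -> ScenarioResult:
    """Main analysis: classify every participant at both timepoints."""
    valuation = valuation or default_valuation_matrix()
    dh = {
        arm: _arm_delta_h(records, arm, valuation, scheme, distress_source)
        for arm in _ARMS
    }
    return _result(1, "main analysis (per participant)", dh["intervention"], dh["control"], _factors(reference))


def scenario2_subgroup_mean(
    summaries: Optional[Mapping[str, Mapping[str, Mapping[str, tuple[float, float, int]]]]] = None,
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    reference: Optional[Mapping[str, object]] = None,
) -> ScenarioResult:
    """Subgroup-mean classification.

    Each CES-D severity subgroup occupies a single health state per
    timepoint: disability fixed by the baseline subgroup (subclinical → I,
    mild/moderate → II, moderate/severe → from its baseline CES-D mean) and
    distress from the timepoint's K10 mean.  Arm totals weight each state
    by the timepoint's subgroup size; the ΔH denominator is the whole-arm n.
    """
    summaries = summaries or SUBGROUP_SUMMARIES
    valuation = valuation or default_valuation_matrix()
    fixed_disability = {"subclinical": Disability.I, "mild_moderate": Disability.II}
    dh: dict[str, float] = {}
    for arm in _ARMS:
        arm_summary = summaries[arm]
        n_arm = {tp: sum(arm_summary[sg][tp][2] for sg in arm_summary) for tp in ("pre", "post")}
        if n_arm["pre"] != n_arm["post"]:
            raise ValueError(
                f"{arm}: subgroup sizes sum to {n_arm['pre']} at pretest but "
                f"{n_arm['post']} at posttest"
            )
        totals = {}
        for tp in ("pre", "post"):
            t = 0.0
            for sg, tps in arm_summary.items():
                cesd_mean, k10_mean, n_sg = tps[tp]
                disability = fixed_disability.get(sg) or scheme.cesd_to_disability(tps["pre"][0])
                state = HealthState(disability, scheme.k10_to_distress(k10_mean))
                t += n_sg * valuation[state]
            totals[tp] = t
        dh[arm] = (totals["post"] - totals["pre"]) / n_arm["pre"]
    return _result(2, "subgroup means", dh["intervention"], dh["control"], _factors(reference))


def scenario3_condition_mean(
    arm_means: Optional[Mapping[str, Mapping[str, float]]] = None,
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    reference: Optional[Mapping[str, object]] = None,
    exact_half_step: bool = False,
) -> ScenarioResult:
    """Whole-arm-mean classification with a half-step adjustment.

    Both timepoints collapse to one state per arm (disability from the
    CES-D mean, distress from the K10 mean).  When the state does not move
    between timepoints, the utility change is taken as half the C→D weight
    gap at the arm's disability level, signed by the direction of the CES-D
    change.  By default the half-gap is rounded to 2 decimals (0.02 at
    disability II) — the granularity at which this judgment-based
    adjustment was defined; ``exact_half_step`` keeps it unrounded.
    """
    arm_means = arm_means or ARM_MEANS
    valuation = valuation or default_valuation_matrix()
    dh: dict[str, float] = {}
    for arm in _ARMS:
        m = arm_means[arm]
        k10_pre = m.get("k10_pre", m.get("k10"))
        k10_post = m.get("k10_post", m.get("k10"))
        pre_state = scheme.classify(m["cesd_pre"], k10_pre)
        post_state = scheme.classify(m["cesd_post"], k10_post)
        if pre_state != post_state:
            dh[arm] = valuation[post_state] - valuation[pre_state]
            continue
        half_gap = (
            valuation[HealthState(pre_state.disability, Distress.C)]
            - valuation[HealthState(pre_state.disability, Distress.D)]
        ) / 2.0
        if not exact_half_step:
            half_gap = round_half_up(half_gap, 2)
        direction = m["cesd_pre"] - m["cesd_post"]  # positive = improvement
        dh[arm] = 0.0 if direction == 0 else (half_gap if direction > 0 else -half_gap)
    return _result(3, "condition means", dh["intervention"], dh["control"], _factors(reference))


def scenario4_frozen_control(
    records: Sequence[ParticipantRecord],
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT,
    reference: Optional[Mapping[str, object]] = None,
) -> ScenarioResult:
    """Main analysis with the control group's change forced to zero."""
    base = scenario1_individual(records, valuation, scheme, distress_source, reference)
    return replace(
        base,
        scenario=4,
        description="main analysis, unchanged control group",
        dh_control=0.0,
        dh_control_ext=0.0,
    )


def scenario5_pretest_extrapolation(
    records: Sequence[ParticipantRecord],
    factors: Optional[Mapping[str, float]] = None,
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    mode: str = "pretest",
) -> ScenarioResult:
    """Predict each participant's 12-month score and re-classify.

    ``mode='pretest'`` (default): predicted CES-D = pretest / arm factor —
    both arms improve, emulating the expected 12-month recovery of an
    untreated control group.  ``mode='posttest'``: the factor is applied to
    posttest scores instead.  Distress keeps the baseline K10 category (no
    12-month distress prediction rule exists).  Results are 12-month values
    by construction, so no further extrapolation is applied.
    """
    factors = dict(factors or SCENARIO5_FACTORS)
    valuation = valuation or default_valuation_matrix()
    if mode not in ("pretest", "posttest"):
        raise ValueError(f"mode must be 'pretest' or 'posttest', got {mode!r}")
    for arm, f in factors.items():
        if f <= 0:
            raise ValueError(f"{arm}: change factor must be positive, got {f}")
    dh: dict[str, float] = {}
    for arm in _ARMS:
        gains = []
        for r in records:
            if r.arm != arm or not r.completer:
                continue
            source = r.cesd_pre if mode == "pretest" else r.cesd_post
            distress = scheme.k10_to_distress(r.k10_pre)
            baseline = HealthState(scheme.cesd_to_disability(r.cesd_pre), distress)
            predicted = HealthState(
                scheme.cesd_to_disability(source / factors[arm]), distress
            )
            gains.append(valuation[predicted] - valuation[baseline])
        if not gains:
            raise ValueError(f"no completer records for arm {arm!r}")
        dh[arm] = sum(gains) / len(gains)
    return _result(
        5,
        f"gain in control group ({mode} extrapolation)",
        dh["intervention"],
        dh["control"],
        factors={},
        already_extrapolated=True,
    )


def run_scenarios(
    records: Sequence[ParticipantRecord],
    scenarios: Iterable[int] = (1, 2, 3, 4, 5),
    valuation: Optional[ValuationMatrix] = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT,
) -> list[ScenarioResult]:
    valuation = valuation or default_valuation_matrix()
    dispatch = {
        1: lambda: scenario1_individual(records, valuation, scheme, distress_source),
        2: lambda: scenario2_subgroup_mean(valuation=valuation, scheme=scheme),
        3: lambda: scenario3_condition_mean(valuation=valuation, scheme=scheme),
        4: lambda: scenario4_frozen_control(records, valuation, scheme, distress_source),
        5: lambda: scenario5_pretest_extrapolation(records, valuation=valuation, scheme=scheme),
    }
    out = []
    for sid in scenarios:
        if sid not in dispatch:
            raise ValueError(f"unknown scenario id {sid}; valid ids are 1-5")
        out.append(dispatch[sid]())
    return out


def scenarios_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Report table: one row per scenario, display-rounded at 3 decimals."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario,
                "description": r.description,
                "dh_intervention": r.dh_intervention,
                "dh_control": r.dh_control,
                "dh_between": r.dh_between,
                "dh_between_extrapolated": r.dh_between_extrapolated,
                "dh_intervention_display": round_half_up(r.dh_intervention, 3),
                "dh_control_display": round_half_up(r.dh_control, 3),
                "dh_between_display": round_half_up(r.dh_between, 3),
                "dh_between_ext_display": round_half_up(r.dh_between_extrapolated, 3),
            }
        )
    return pd.DataFrame(rows)
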