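"""Published inputs of the Norwegian translated-program prevention trial.

The trial's raw participant data were never deposited; what is public are
summary tables — per-arm health-state counts at both timepoints, CES-D
subgroup summaries, reference-trial 12-month outcomes, cost figures and
QALY monetary values.  This module ships those printed figures as named
constants so the analysis can be reproduced from them, and provides
:func:`reference_records`, which rebuilds a participant-level dataset whose
state cross-tabulations match the published counts exactly (any quantity
that depends only on the per-timepoint state marginals is then identical to
the original analysis).
"""

from __future__ import annotations

from typing import Mapping

from .costs import CostSchedule
from .extrapolation import ReferenceOutcome
from .scales import Disability, Distress, HealthState, ParticipantRecord
from .valuation import DescriptiveMatrix

__all__ = [
    "STATE_COUNTS",
    "state_count_matrices",
    "reference_records",
    "SUBGROUP_SUMMARIES",
    "ARM_MEANS",
    "REFERENCE_OUTCOMES",
    "COST_SCHEDULES",
    "QALY_VALUES_K_EUR",
    "PERSONS_TREATED_GRID",
    "SCENARIO5_FACTORS",
    "INFLATION_RATES",
]


def _counts(table: Mapping[str, Mapping[str, int]]) -> dict[HealthState, int]:
    return {
        HealthState(Disability[d], Distress[k]): n
        for d, row in table.items()
        for k, n in row.items()
    }


# Participant counts per (disability, distress) state, per arm and timepoint,
# as published.  Intervention n=43, control n=59 (completers).
STATE_COUNTS: dict[tuple[str, str], dict[HealthState, int]] = {
    ("intervention", "pre"): _counts(
        {
            "I": {"A": 1, "B": 8, "C": 5},
            "II": {"B": 6, "C": 3, "D": 1},
            "III": {"B": 3, "C": 4, "D": 3},
            "IV": {"B": 2, "D": 5},
            "V": {"D": 2},
        }
    ),
    ("intervention", "post"): _counts(
        {
            "I": {"A": 1, "B": 12, "C": 8, "D": 1},
            "II": {"B": 4, "C": 2, "D": 1},
            "III": {"B": 2, "C": 1, "D": 2},
            "IV": {"B": 1, "C": 1, "D": 5},
            "V": {"D": 2},
        }
    ),
    ("control", "pre"): _counts(
        {
            "I": {"A": 1, "B": 11, "C": 10, "D": 3},
            "II": {"B": 7, "C": 4, "D": 6},
            "III": {"B": 1, "C": 7, "D": 6},
            "IV": {"B": 1},
            "V": {"B": 1, "D": 1},
        }
    ),
    # NOTE: these counts imply a posttest total QOL of 56.06, while the source
    # prints 55.96 — a probable misprint in one published cell.  The package
    # reproduces what the printed counts imply.
    ("control", "post"): _counts(
        {
            "I": {"B": 10, "C": 12, "D": 3},
            "II": {"B": 6, "C": 3, "D": 2},
            "III": {"A": 1, "B": 3, "C": 1, "D": 5},
            "IV": {"B": 1, "C": 5, "D": 3},
            "V": {"D": 3},
            "VI": {"B": 1},
        }
    ),
}


def state_count_matrices() -> dict[tuple[str, str], DescriptiveMatrix]:
    """The published counts as validated :class:`DescriptiveMatrix` objects."""
    return {
        (arm, tp): DescriptiveMatrix(counts=c, arm=arm, timepoint=tp)
        for (arm, tp), c in STATE_COUNTS.items()
    }


def reference_records() -> list[ParticipantRecord]:
    """Participant-level records regenerated from the published state counts."""
    from .simulate import FixtureSpec, generate_from_matrix  # cycle guard

    m = state_count_matrices()
    records: list[ParticipantRecord] = []
    for arm in ("intervention", "control"):
        records.extend(
            generate_from_matrix(
                FixtureSpec(pre=m[(arm, "pre")], post=m[(arm, "post")]),
                id_prefix=arm[:3],
            )
        )
    return records


# CES-D severity-subgroup summaries per arm: (CES-D mean, K10 mean, n) at
# each timepoint, as published.  Subgroup membership (and hence disability
# category) is fixed at baseline; K10 means move between timepoints.
SUBGROUP_SUMMARIES: dict[str, dict[str, dict[str, tuple[float, float, int]]]] = {
    "intervention": {
        "subclinical": {"pre": (11.4, 22.8, 14), "post": (10.0, 23.7, 22)},
        "mild_moderate": {"pre": (19.0, 24.4, 10), "post": (11.0, 25.3, 7)},
        "moderate_severe": {"pre": (32.7, 30.0, 19), "post": (28.6, 30.7, 14)},
    },
    "control": {
        "subclinical": {"pre": (9.8, 24.5, 25), "post": (14.4, 25.4, 25)},
        "mild_moderate": {"pre": (19.2, 27.5, 17), "post": (19.5, 25.1, 11)},
        "moderate_severe": {"pre": (30.4, 28.5, 17), "post": (32.4, 28.3, 23)},
    },
}

# Whole-arm CES-D means pre/post and the (baseline) K10 mean, as published.
ARM_MEANS: dict[str, dict[str, float]] = {
    "intervention": {"cesd_pre": 22.6, "cesd_post": 18.5, "k10": 33.2},
    "control": {"cesd_pre": 18.5, "cesd_post": 21.4, "k10": 33.2},
}

# Reference 12-month trial of the same programs (posttest → 12-month CES-D
# means), the basis of the per-arm change factors (≈1.128 and ≈1.189).
REFERENCE_OUTCOMES: dict[str, ReferenceOutcome] = {
    "intervention": ReferenceOutcome(post_mean=15.9, followup_mean=14.1, arm_label="mackinnon_12m_intervention"),
    "control": ReferenceOutcome(post_mean=19.5, followup_mean=16.4, arm_label="mackinnon_12m_control"),
}

# Published € cost figures (in €1000), 3-year operating period.
COST_SCHEDULES: dict[str, CostSchedule] = {
    "translation_norway": CostSchedule(development=95.9, maintenance=14.0, service_fee=9.0, operating_years=3),
    "development_australia": CostSchedule(development=479.4, maintenance=44.7, service_fee=0.0, operating_years=3),
}

# Societal value of one QALY (€1000): Norwegian proposal and UK NICE threshold.
QALY_VALUES_K_EUR: dict[str, float] = {"norwegian": 67.0, "uk": 30.0}

PERSONS_TREATED_GRID: tuple[int, ...] = (1000, 20000)

# Pretest → predicted-12-month change factors used by sensitivity scenario 5.
SCENARIO5_FACTORS: dict[str, float] = {"intervention": 1.546, "control": 1.317}

# Average annual consumer-price-index rates used for the historical amounts.
INFLATION_RATES: dict[str, float] = {"NOK": 0.023, "AUD": 0.029}
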