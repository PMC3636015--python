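"""Cost-effectiveness arithmetic: savings, QALYs gained, CER, break-even.

Inputs are the societal value of one QALY, the number of treated persons
needed to gain one QALY, the mean annual cost of the program, and the number
of persons treated per year (monetary figures in €1000).  The chain is:

    savings per person = value_per_qaly / persons_per_qaly - cost / persons
    total savings      = savings per person x persons treated
    QALYs gained       = total savings / value_per_qaly
    CER                = cost / QALYs gained          (reported in €/QALY)

Nothing is rounded inside the chain; only display values are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._rounding import ceil_guarded, round_half_up

__all__ = [
    "CeInputs",
    "CeResult",
    "savings_per_person",
    "total_savings",
    "qalys_gained",
    "cer",
    "break_even_persons",
    "return_multiple",
    "evaluate",
    "ce_table",
]


@dataclass(frozen=True)
class CeInputs:
    """One scenario row: QALY value, persons/QALY, annual cost, uptake."""

    savings_per_qaly: float  # €1000 per QALY
    persons_per_qaly: int
    dev_cost: float  # €1000, mean annual cost of the program
    persons_treated: int  # persons per year

    def __post_init__(self) -> None:
        bad = [
            name
            for name in ("savings_per_qaly", "persons_per_qaly", "dev_cost", "persons_treated")
            if getattr(self, name) <= 0
        ]
        if bad:
            raise ValueError(f"CE inputs must be strictly positive: {bad}")


def savings_per_person(inputs: CeInputs) -> float:
    """Per-person net savings (€1000/person/year)."""
    return (
        inputs.savings_per_qaly / inputs.persons_per_qaly
        - inputs.dev_cost / inputs.persons_treated
    )


def total_savings(inputs: CeInputs) -> float:
    """Annual net savings over everyone treated (€1000/year)."""
    return savings_per_person(inputs) * inputs.persons_treated


def qalys_gained(inputs: CeInputs) -> float:
    """QALYs represented by the total savings."""
    return total_savings(inputs) / inputs.savings_per_qaly


def cer(inputs: CeInputs) -> float:
    """Cost-effectiveness ratio in € per QALY (note: €, not €1000)."""
    q = qalys_gained(inputs)
    if q <= 0:
        raise ValueError(
            "CER undefined: the program does not gain QALYs at these inputs"
        )
    return inputs.dev_cost / q * 1000.0


def break_even_persons(
    savings_per_qaly: float, persons_per_qaly: int, dev_cost: float
) -> int:
    """Annual number treated at which monetized gains cover the annual cost.

    Ceiling of cost / (value per QALY / persons per QALY).
    """
    if min(savings_per_qaly, persons_per_qaly, dev_cost) <= 0:
        raise ValueError("all break-even inputs must be positive")
    return ceil_guarded(dev_cost / savings_per_qaly * persons_per_qaly)


def return_multiple(total_savings_value: float, dev_cost: float) -> int:
    """How many times the annual cost is returned (round half-up)."""
    if dev_cost <= 0:
        raise ValueError("dev_cost must be positive")
    return int(round_half_up(total_savings_value / dev_cost, 0))


@dataclass(frozen=True)
class CeResult:
    """Unrounded results of the CE chain for one scenario row.

    ``cer`` is None when the row is dominated (no QALYs gained at these
    inputs), in which case no finite cost per QALY exists.
    """

    inputs: CeInputs
    savings_per_person: float  # €1000
    total_savings: float  # €1000
    qalys: float
    cer: Optional[float]  # € per QALY


def evaluate(inputs: CeInputs) -> CeResult:
    q = qalys_gained(inputs)
    return CeResult(
        inputs=inputs,
        savings_per_person=savings_per_person(inputs),
        total_savings=total_savings(inputs),
        qalys=q,
        cer=cer(inputs) if q > 0 else None,
    )


def ce_table(
    qaly_values: Mapping[str, float],
    cost_schedules: Mapping[str, float],
    persons_treated: Sequence[int],
    persons_per_qaly: int,
) -> pd.DataFrame:
    """Grid of CE results over QALY values x cost schedules x uptake levels.

    ``cost_schedules`` maps a project label to its mean annual cost (€1000),
    conventionally the value as displayed at one decimal in the cost table —
    published CERs derive from the displayed cost figures.  Returns display-
    rounded columns alongside the unrounded ones.
    """
    rows = []
    for project, cost in cost_schedules.items():
        for estimate, value in qaly_values.items():
            for persons in persons_treated:
                res = evaluate(
                    CeInputs(
                        savings_per_qaly=value,
                        persons_per_qaly=persons_per_qaly,
                        dev_cost=cost,
                        persons_treated=persons,
                    )
                )
                rows.append(
                    {
                        "project": project,
                        "estimate": estimate,
                        "savings_per_qaly": value,
                        "persons_per_qaly": persons_per_qaly,
                        "annual_cost": cost,
                        "persons_treated": persons,
                        "savings_per_person": res.savings_per_person,
                        "total_savings": res.total_savings,
                        "qalys": res.qalys,
                        "cer": res.cer,
                        "savings_per_person_display": round_half_up(
                            res.savings_per_person, 2
                        ),
                        "total_savings_display": int(round_half_up(res.total_savings, 0)),
                        "qalys_display": int(round_half_up(res.qalys, 0)),
                        "cer_display": None if res.cer is None else int(round_half_up(res.cer, 0)),
                    }
                )
    return pd.DataFrame(rows)
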