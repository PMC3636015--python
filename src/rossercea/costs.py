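"""Cost modelling: inflation adjustment, currency conversion, amortization.

All monetary arithmetic is carried in thousands of euro (€1000) at full
precision; table-style display rounds to one decimal.  Historical amounts in
other currencies are brought to a common price level with a constant annual
consumer-price-index rate and converted at a dated exchange rate, rounded
*up* to a configurable granularity (conservative costing: never understate a
cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "CostEntry",
    "CostSchedule",
    "AmortizedCost",
    "adjust_inflation",
    "convert_currency",
    "amortize",
    "cost_ratio",
]


@dataclass(frozen=True)
class CostEntry:
    amount: float
    currency: str
    base_year: int

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"cost amount must be >= 0, got {self.amount}")


def adjust_inflation(entry: CostEntry, annual_rate: float, target_year: int) -> CostEntry:
    """Compound ``entry`` forward to ``target_year`` at a constant CPI rate."""
    if annual_rate <= -1:
        raise ValueError(f"annual rate must exceed -100%, got {annual_rate}")
    if target_year < entry.base_year:
        raise ValueError(
            f"target year {target_year} precedes base year {entry.base_year}"
        )
    factor = (1.0 + annual_rate) ** (target_year - entry.base_year)
    return replace(entry, amount=entry.amount * factor, base_year=target_year)


def convert_currency(entry: CostEntry, rate: float, round_to: float = 0.1) -> CostEntry:
    """Convert to euro at ``rate`` and round up to the nearest ``round_to``.

    ``round_to`` is in the same (€1000 or €) units as the amounts; e.g. with
    amounts in €, ``round_to=100`` rounds up to the nearest €100.
    """
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    if round_to <= 0:
        raise ValueError(f"round_to must be positive, got {round_to}")
    raw = entry.amount * rate
    rounded = math.ceil(round(raw / round_to, 9)) * round_to
    return CostEntry(amount=rounded, currency="EUR", base_year=entry.base_year)


@dataclass(frozen=True)
class CostSchedule:
    """Annual cost structure: one-off development (year 1) plus recurring
    maintenance and service fees, over a fixed operating period."""

    development: float
    maintenance: float
    service_fee: float = 0.0
    operating_years: int = 3

    def __post_init__(self) -> None:
        for name in ("development", "maintenance", "service_fee"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.operating_years < 1:
            raise ValueError("operating_years must be >= 1")


@dataclass(frozen=True)
class AmortizedCost:
    per_year_totals: Sequence[float]
    mean_annual: float


def amortize(schedule: CostSchedule) -> AmortizedCost:
    """Spread the schedule over its operating period.

    Year 1 carries development + recurring costs; later years recurring
    only.  The mean annual cost is the grand total over operating years.
    """
    recurring = schedule.maintenance + schedule.service_fee
    per_year = [schedule.development + recurring] + [recurring] * (
        schedule.operating_years - 1
    )
    return AmortizedCost(
        per_year_totals=tuple(per_year),
        mean_annual=math.fsum(per_year) / schedule.operating_years,
    )


def cost_ratio(a: AmortizedCost, b: AmortizedCost) -> float:
    """Mean-annual cost of ``a`` as a percentage of ``b``."""
    if b.mean_annual <= 0:
        raise ValueError("reference mean annual cost must be positive")
    return 100.0 * a.mean_annual / b.mean_annual
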