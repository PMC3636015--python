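"""Extrapolation of an 8-week utility gain to a 12-month QALY gain.

The trial measured change over 8 weeks only.  A reference trial of the same
programs with a 12-month follow-up supplies, per arm, the ratio of the
posttest CES-D mean to the 12-month mean — the *change factor*.  A positive
short-term ΔH is multiplied by the factor (the improvement continues); a
negative ΔH is multiplied by the reciprocal (a deteriorated group is expected
to recover), which shrinks the between-group gap.  QALY gain is then
ΔH x T with T the horizon in years.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import ceil_guarded
from .scales import CESD_MAX, CESD_MIN
from .valuation import DeltaH

__all__ = [
    "ReferenceOutcome",
    "change_factor",
    "extrapolate_delta_h",
    "QalyGain",
    "qaly_gain",
    "persons_per_qaly",
]


@dataclass(frozen=True)
class ReferenceOutcome:
    """Posttest and 12-month CES-D means of one reference-trial arm."""

    post_mean: float
    followup_mean: float
    arm_label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("post_mean", self.post_mean), ("followup_mean", self.followup_mean)):
            if not CESD_MIN <= v <= CESD_MAX:
                raise ValueError(f"{name} {v} outside the CES-D range")


def change_factor(ref: ReferenceOutcome) -> float:
    """Posttest mean / 12-month mean; > 1 means continued improvement.

    Kept at full precision — published factors such as 1.127 are display
    truncations of this ratio and are never used for onward arithmetic.
    """
    if ref.followup_mean <= 0:
        raise ValueError(f"follow-up mean must be positive, got {ref.followup_mean}")
    return ref.post_mean / ref.followup_mean


def extrapolate_delta_h(dh: DeltaH, factor: float) -> DeltaH:
    """Scale an 8-week ΔH to 12 months.

    Sign-preserving: gains are multiplied by ``factor``, losses by
    ``1/factor`` (the reciprocal rule for a group expected to recover).
    """
    if factor <= 0:
        raise ValueError(f"change factor must be positive, got {factor}")
    scaled = dh.value * factor if dh.value >= 0 else dh.value / factor
    return DeltaH(value=scaled, scope=dh.scope)


@dataclass(frozen=True)
class QalyGain:
    """QALY gain = ΔH x T (T in years)."""

    delta_h: float
    horizon_years: float

    @property
    def value(self) -> float:
        return self.delta_h * self.horizon_years


def qaly_gain(dh: DeltaH, horizon_years: float = 1.0) -> QalyGain:
    if horizon_years <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_years}")
    return QalyGain(delta_h=dh.value, horizon_years=horizon_years)


def persons_per_qaly(gain: QalyGain) -> int:
    """Number of treated persons needed to accrue one whole QALY.

    Ceiling of 1/gain: a fraction of a person cannot be treated, so the
    count is rounded up.
    """
    if gain.value <= 0:
        raise ValueError("persons per QALY is undefined for a non-positive gain")
    return ceil_guarded(1.0 / gain.value)
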