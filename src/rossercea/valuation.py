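"""Descriptive health-state matrices and Rosser utility valuation.

The quality-of-life (QOL) total for a group at one timepoint is the sum over
all health states of (participant count in that state) x (utility weight of
that state), where weights come from the Rosser valuation matrix (1 = a year
of perfect health, 0 = dead).  Dividing the change in total QOL by the group
size gives the mean utility gain ΔH, the quantity that drives the QALY
arithmetic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .scales import (
    ALL_STATES,
    ARMS,
    TIMEPOINTS,
    CategoryScheme,
    DEFAULT_SCHEME,
    Disability,
    Distress,
    DistressSource,
    HealthState,
    ParticipantRecord,
    classify_record,
)

__all__ = [
    "ValuationMatrix",
    "DescriptiveMatrix",
    "GroupQol",
    "DeltaH",
    "load_valuation_matrix",
    "default_valuation_matrix",
    "build_descriptive_matrix",
    "total_qol",
    "delta_h",
    "between_groups_delta_h",
]


@dataclass(frozen=True)
class ValuationMatrix:
    """Utility weight per Rosser health state.

    Validation enforces the Rosser conventions: the best state (I, A) has
    weight 1, the worst implemented state (VI, D) has weight 0, all weights
    lie in [0, 1], and weights are non-increasing with worsening disability
    (down a column) and worsening distress (along a row).
    """

    weights: Mapping[HealthState, float]

    def __post_init__(self) -> None:
        problems: list[str] = []
        missing = [str(s) for s in ALL_STATES if s not in self.weights]
        if missing:
            raise ValueError(f"valuation matrix missing states: {missing}")
        for s in ALL_STATES:
            w = self.weights[s]
            if not 0.0 <= w <= 1.0:
                problems.append(f"{s}: weight {w} outside [0, 1]")
        if self.weights[HealthState(Disability.I, Distress.A)] != 1.0:
            problems.append("state IA must carry weight 1.000")
        if self.weights[HealthState(Disability.VI, Distress.D)] != 0.0:
            problems.append("state VID must carry weight 0.000")
        for d in Disability:
            for a, b in zip(list(Distress)[:-1], list(Distress)[1:]):
                if self.weights[HealthState(d, a)] < self.weights[HealthState(d, b)]:
                    problems.append(f"row {d}: weight increases from {a} to {b}")
        for k in Distress:
            for a, b in zip(list(Disability)[:-1], list(Disability)[1:]):
                if self.weights[HealthState(a, k)] < self.weights[HealthState(b, k)]:
                    problems.append(f"column {k}: weight increases from {a} to {b}")
        if problems:
            raise ValueError("invalid valuation matrix: " + "; ".join(problems))

    def __getitem__(self, state: HealthState) -> float:
        return self.weights[state]

    def to_frame(self) -> pd.DataFrame:
        """Grid layout: rows = disability I-VI, columns = distress A-D."""
        return pd.DataFrame(
            [[self.weights[HealthState(d, k)] for k in Distress] for d in Disability],
            index=[str(d) for d in Disability],
            columns=[str(k) for k in Distress],
        )


def _matrix_from_frame(df: pd.DataFrame) -> ValuationMatrix:
    df = df.set_index("disability") if "disability" in df.columns else df
    weights = {}
    for d in Disability:
        for k in Distress:
            try:
                weights[HealthState(d, k)] = float(df.loc[str(d), str(k)])
            except KeyError:
                pass  # caught by ValuationMatrix validation
    return ValuationMatrix(weights)


def load_valuation_matrix(source: Optional[str | Path] = None) -> ValuationMatrix:
    """Load a valuation matrix from CSV (rows I-VI, columns A-D).

    With no ``source`` the packaged Rosser matrix is returned.
    """
    if source is None:
        return default_valuation_matrix()
    return _matrix_from_frame(pd.read_csv(source))


def default_valuation_matrix() -> ValuationMatrix:
    """The packaged Rosser utility valuation matrix (3-decimal weights)."""
    ref = resources.files("rossercea.data").joinpath("rosser_valuation.csv")
    with resources.as_file(ref) as path:
        return _matrix_from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class DescriptiveMatrix:
    """Participant counts per health state for one arm at one timepoint."""

    counts: Mapping[HealthState, int]
    arm: str
    timepoint: str
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        bad = [str(s) for s in self.counts if s not in ALL_STATES]
        if bad:
            raise ValueError(f"counts over unimplemented states: {bad}")
        if any(c < 0 or c != int(c) for c in self.counts.values()):
            raise ValueError("counts must be non-negative integers")
        n = sum(int(c) for c in self.counts.values())
        if n < 1:
            raise ValueError("a descriptive matrix needs at least one participant")
        object.__setattr__(self, "n", n)

    def to_frame(self) -> pd.DataFrame:
        """Grid layout for human diffing: rows = disability, cols = distress."""
        return pd.DataFrame(
            [
                [int(self.counts.get(HealthState(d, k), 0)) for k in Distress]
                for d in Disability
            ],
            index=[str(d) for d in Disability],
            columns=[str(k) for k in Distress],
        )


def build_descriptive_matrix(
    records: Iterable[ParticipantRecord],
    arm: str,
    timepoint: str,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT,
) -> DescriptiveMatrix:
    """Cross-tabulate completers of ``arm`` into health states at ``timepoint``."""
    counts: dict[HealthState, int] = {}
    for r in records:
        if r.arm != arm or not r.completer:
            continue
        state = classify_record(r, timepoint, scheme, distress_source)
        counts[state] = counts.get(state, 0) + 1
    if not counts:
        raise ValueError(f"no completer records for arm {arm!r}")
    return DescriptiveMatrix(counts=counts, arm=arm, timepoint=timepoint)


@dataclass(frozen=True)
class GroupQol:
    """Total and mean utility for one group at one timepoint."""

    total: float
    n: int

    @property
    def mean(self) -> float:
        return self.total / self.n


@dataclass(frozen=True)
class DeltaH:
    """Mean utility change (dimensionless, |value| <= 1).

    ``scope`` distinguishes a within-group pre/post change from the
    between-groups contrast of two such changes.
    """

    value: float
    scope: str = "within_group"

    def __post_init__(self) -> None:
        if self.scope not in ("within_group", "between_groups"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if abs(self.value) > 1.0 + 1e-12:
            raise ValueError(f"|ΔH| cannot exceed 1, got {self.value}")


def total_qol(matrix: DescriptiveMatrix, valuation: ValuationMatrix) -> GroupQol:
    """Count-weighted sum of utility weights over all occupied states."""
    total = math.fsum(c * valuation[s] for s, c in matrix.counts.items())
    return GroupQol(total=total, n=matrix.n)


def delta_h(pre: GroupQol, post: GroupQol) -> DeltaH:
    """Within-group mean utility change from unrounded totals."""
    if pre.n != post.n:
        raise ValueError(
            f"pre (n={pre.n}) and post (n={post.n}) must cover the same completer set"
        )
    return DeltaH(value=(post.total - pre.total) / pre.n, scope="within_group")


def between_groups_delta_h(intervention: DeltaH, control: DeltaH) -> DeltaH:
    """Between-groups contrast: intervention ΔH minus control ΔH."""
    for dh, label in ((intervention, "intervention"), (control, "control")):
        if dh.scope != "within_group":
            raise ValueError(f"{label} ΔH must be within_group, got {dh.scope!r}")
    return DeltaH(value=intervention.value - control.value, scope="between_groups")
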