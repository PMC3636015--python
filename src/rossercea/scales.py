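"""Mapping of depression-scale scores onto Rosser Index categories.

The Rosser Index classifies health into a disability dimension (categories
I-VIII, of which only I-VI describe ambulatory states and are used here) and
a distress dimension (A-D).  In this analysis the disability dimension is
operationalised through the CES-D total score (0-60) and the distress
dimension through the K10 total score (10-50).

Category boundaries are half-open real intervals extending the published
integer bands, so that non-integer subgroup means (e.g. a CES-D mean of
32.7 or a K10 mean of 24.5) classify consistently with raw integer scores.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Disability",
    "Distress",
    "CesdSubgroup",
    "HealthState",
    "ParticipantRecord",
    "CategoryScheme",
    "DEFAULT_SCHEME",
    "DistressSource",
    "cesd_to_disability",
    "cesd_to_subgroup",
    "k10_to_distress",
    "classify",
    "classify_record",
    "read_participants",
    "write_participants",
    "ALL_STATES",
]

CESD_MIN, CESD_MAX = 0.0, 60.0
K10_MIN, K10_MAX = 10.0, 50.0


class Disability(enum.IntEnum):
    """Rosser disability category (I = no social disability ... VI = full-time
    care / institutionalised).  Categories VII-VIII (confined to bed,
    unconscious) are outside the scope of a depression-symptom mapping and
    are never constructed."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6

    def __str__(self) -> str:  # roman label, as printed in the matrices
        return self.name


class Distress(enum.IntEnum):
    """Rosser distress category (A = none ... D = severe)."""

    A = 1
    B = 2
    C = 3
    D = 4

    def __str__(self) -> str:
        return self.name


class CesdSubgroup(enum.Enum):
    """Depression-severity strata of the CES-D (Rushton-style bands)."""

    SUBCLINICAL = "subclinical"
    MILD_MODERATE = "mild_moderate"
    MODERATE_SEVERE = "moderate_severe"


@dataclass(frozen=True, order=True)
class HealthState:
    """One cell of the Rosser health-state matrix."""

    disability: Disability
    distress: Distress

    def __str__(self) -> str:
        return f"{self.disability}{self.distress}"


ALL_STATES: tuple[HealthState, ...] = tuple(
    HealthState(d, s) for d in Disability for s in Distress
)


class DistressSource(enum.Enum):
    """Which K10 assessment drives the distress category at posttest.

    ``PER_TIMEPOINT`` uses the timepoint's own K10 when present (falling back
    to baseline); ``BASELINE_ONLY`` always classifies distress from the
    preassessment K10.
    """

    PER_TIMEPOINT = "per_timepoint"
    BASELINE_ONLY = "baseline_only"


def _check_range(value: float, lo: float, hi: float, name: str) -> float:
    value = float(value)
    if not lo <= value <= hi:
        raise ValueError(f"{name} score {value!r} outside valid range [{lo:g}, {hi:g}]")
    return value


@dataclass(frozen=True)
class CategoryScheme:
    """Interval boundaries mapping scale scores to Rosser categories.

    ``cesd_disability_edges`` are the lower edges of categories II..VI (a
    score below the first edge is category I; at or above the last, VI).
    Likewise for the other edge sequences.  All intervals are half-open
    ``[edge_k, edge_{k+1})`` except the topmost, which is closed at the
    instrument maximum.
    """

    cesd_disability_edges: Sequence[float] = (16.0, 24.0, 34.0, 43.0, 53.0)
    cesd_subgroup_edges: Sequence[float] = (16.0, 24.0)
    k10_distress_edges: Sequence[float] = (20.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        for name, edges, lo, hi, k in (
            ("cesd_disability_edges", self.cesd_disability_edges, CESD_MIN, CESD_MAX, 5),
            ("cesd_subgroup_edges", self.cesd_subgroup_edges, CESD_MIN, CESD_MAX, 2),
            ("k10_distress_edges", self.k10_distress_edges, K10_MIN, K10_MAX, 3),
        ):
            if len(edges) != k:
                raise ValueError(f"{name} needs exactly {k} edges, got {len(edges)}")
            if list(edges) != sorted(edges) or len(set(edges)) != k:
                raise ValueError(f"{name} must be strictly increasing: {edges}")
            if edges[0] <= lo or edges[-1] > hi:
                raise ValueError(f"{name} must lie inside ({lo:g}, {hi:g}]: {edges}")

    @staticmethod
    def _bin(value: float, edges: Sequence[float]) -> int:
        i = 0
        for e in edges:
            if value >= e:
                i += 1
        return i

    def cesd_to_disability(self, score: float) -> Disability:
        score = _check_range(score, CESD_MIN, CESD_MAX, "CES-D")
        return Disability(self._bin(score, self.cesd_disability_edges) + 1)

    def cesd_to_subgroup(self, score: float) -> CesdSubgroup:
        score = _check_range(score, CESD_MIN, CESD_MAX, "CES-D")
        return list(CesdSubgroup)[self._bin(score, self.cesd_subgroup_edges)]

    def k10_to_distress(self, score: float) -> Distress:
        score = _check_range(score, K10_MIN, K10_MAX, "K10")
        return Distress(self._bin(score, self.k10_distress_edges) + 1)

    def classify(self, cesd: float, k10: float) -> HealthState:
        return HealthState(self.cesd_to_disability(cesd), self.k10_to_distress(k10))

    def representative_scores(self, state: HealthState) -> tuple[float, float]:
        """Interval midpoints of ``state`` — a (CES-D, K10) pair guaranteed to
        classify back to ``state``.  Used by the fixture generator."""
        d_edges = [CESD_MIN, *self.cesd_disability_edges, CESD_MAX]
        k_edges = [K10_MIN, *self.k10_distress_edges, K10_MAX]
        di = int(state.disability) - 1
        ki = int(state.distress) - 1
        return (
            (d_edges[di] + d_edges[di + 1]) / 2.0,
            (k_edges[ki] + k_edges[ki + 1]) / 2.0,
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "CategoryScheme":
        return cls(**{k: tuple(v) for k, v in d.items()})


DEFAULT_SCHEME = CategoryScheme()


def cesd_to_disability(score: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> Disability:
    """Map a CES-D total score (or subgroup mean) to a disability category."""
    return scheme.cesd_to_disability(score)


def cesd_to_subgroup(score: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> CesdSubgroup:
    """Map a CES-D total score to its severity stratum."""
    return scheme.cesd_to_subgroup(score)


def k10_to_distress(score: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> Distress:
    """Map a K10 total score (or mean) to a distress category."""
    return scheme.k10_to_distress(score)


def classify(cesd: float, k10: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> HealthState:
    """Classify a (CES-D, K10) score pair into a Rosser health state."""
    return scheme.classify(cesd, k10)


ARMS = ("intervention", "control")
TIMEPOINTS = ("pre", "post")


@dataclass(frozen=True)
class ParticipantRecord:
    """One trial participant's arm assignment and scale scores.

    ``completer`` implies both posttest scores may be classified; a completer
    without a posttest CES-D is rejected at construction.
    """

    id: str
    arm: str
    cesd_pre: float
    k10_pre: float
    cesd_post: Optional[float] = None
    k10_post: Optional[float] = None
    completer: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        _check_range(self.cesd_pre, CESD_MIN, CESD_MAX, "CES-D")
        _check_range(self.k10_pre, K10_MIN, K10_MAX, "K10")
        if self.cesd_post is not None:
            _check_range(self.cesd_post, CESD_MIN, CESD_MAX, "CES-D")
        if self.k10_post is not None:
            _check_range(self.k10_post, K10_MIN, K10_MAX, "K10")
        if self.completer and self.cesd_post is None:
            raise ValueError(f"record {self.id!r}: completer without a posttest CES-D score")


def classify_record(
    record: ParticipantRecord,
    timepoint: str,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT,
) -> HealthState:
    """Health state of one participant at ``timepoint`` ('pre' or 'post')."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {timepoint!r}")
    if timepoint == "pre":
        return scheme.classify(record.cesd_pre, record.k10_pre)
    if record.cesd_post is None:
        raise ValueError(f"record {record.id!r} has no posttest CES-D score")
    k10 = record.k10_pre
    if distress_source is DistressSource.PER_TIMEPOINT and record.k10_post is not None:
        k10 = record.k10_post
    return scheme.classify(record.cesd_post, k10)


_CSV_COLUMNS = ["id", "arm", "cesd_pre", "cesd_post", "k10_pre", "k10_post", "completer"]


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read the participant CSV (header row; empty cell = missing score)."""
    records: list[ParticipantRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"participant CSV missing columns: {sorted(missing)}")
        for row in reader:
            def num(key: str) -> Optional[float]:
                v = (row.get(key) or "").strip()
                return float(v) if v else None

            cesd_pre, k10_pre = num("cesd_pre"), num("k10_pre")
            if cesd_pre is None or k10_pre is None:
                raise ValueError(f"record {row.get('id')!r}: baseline scores are required")
            records.append(
                ParticipantRecord(
                    id=row["id"],
                    arm=row["arm"].strip().lower(),
                    cesd_pre=cesd_pre,
                    cesd_post=num("cesd_post"),
                    k10_pre=k10_pre,
                    k10_post=num("k10_post"),
                    completer=row["completer"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return records


def write_participants(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.arm,
                    f"{r.cesd_pre:g}",
                    "" if r.cesd_post is None else f"{r.cesd_post:g}",
                    f"{r.k10_pre:g}",
                    "" if r.k10_post is None else f"{r.k10_post:g}",
                    "true" if r.completer else "false",
                ]
            )
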