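"""Synthetic two-arm trial data with the structure the analysis assumes.

Two generators:

* :func:`generate_trial` draws participant records from configurable
  moments — truncated-normal baselines (CES-D correlated with K10), a
  normal per-arm change applied to the posttest, Bernoulli retention.
  Defaults reproduce the published trial conditions (intervention n=81
  enrolled / 53% retained, control n=82 / 72% retained, the published
  baseline and change-score moments).

* :func:`generate_from_matrix` inverts the descriptive cross-tabulation:
  given per-timepoint state counts it emits records whose scores are the
  category-interval midpoints, so re-classification reproduces the input
  counts exactly (round-trip identity).  Only the per-timepoint marginals
  are meaningful; the pre→post pairing of states is a greedy convention,
  which is inert for every marginal-dependent quantity (totals, ΔH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .scales import (
    CESD_MAX,
    CESD_MIN,
    K10_MAX,
    K10_MIN,
    CategoryScheme,
    DEFAULT_SCHEME,
    HealthState,
    ParticipantRecord,
)
from .valuation import DescriptiveMatrix

__all__ = ["ArmConfig", "TrialConfig", "FixtureSpec", "generate_trial", "generate_from_matrix"]


@dataclass(frozen=True)
class ArmConfig:
    """Moments for one arm: baseline means/SDs, pre-post change, retention."""

    n: int
    cesd_mean: float
    cesd_sd: float
    k10_mean: float
    k10_sd: float
    change_mean: float  # mean CES-D improvement (pre - post)
    change_sd: float
    retention: float  # fraction of completers, in (0, 1]

    def validate(self, label: str) -> list[str]:
        problems = []
        if self.n < 1:
            problems.append(f"{label}.n must be >= 1")
        for nm in ("cesd_sd", "k10_sd", "change_sd"):
            if getattr(self, nm) < 0:
                problems.append(f"{label}.{nm} must be >= 0")
        if not 0 < self.retention <= 1:
            problems.append(f"{label}.retention must be in (0, 1]")
        return problems


@dataclass(frozen=True)
class TrialConfig:
    """Full two-arm configuration.

    ``correlation`` is the latent baseline correlation between CES-D and
    K10; 0.6 by default, a typical association between depression-symptom
    and general-distress scales in community samples.
    """

    intervention: ArmConfig = ArmConfig(
        n=81, cesd_mean=22.6, cesd_sd=10.9, k10_mean=33.2, k10_sd=5.5,
        change_mean=4.1, change_sd=10.4, retention=43 / 81,
    )
    control: ArmConfig = ArmConfig(
        n=82, cesd_mean=18.5, cesd_sd=9.6, k10_mean=33.2, k10_sd=5.0,
        change_mean=-3.0, change_sd=9.1, retention=59 / 82,
    )
    correlation: float = 0.6
    seed: int = 0

    def validate(self) -> list[str]:
        problems = self.intervention.validate("intervention") + self.control.validate("control")
        if not -1 <= self.correlation <= 1:
            problems.append("correlation must be in [-1, 1]")
        return problems


def generate_trial(config: TrialConfig) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic trial from ``config``.

    Baselines are truncated-normal within the instrument ranges with the
    configured CES-D/K10 correlation (Gaussian copula on the latent scale).
    The posttest is pre minus a normal change draw, clipped to range; the
    K10 posttest tracks the CES-D change through the correlation slope plus
    independent noise.  Non-completers keep their baseline only.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid trial config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    rho = config.correlation
    records: list[ParticipantRecord] = []
    for arm_name, arm in (("intervention", config.intervention), ("control", config.control)):
        z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=arm.n)
        u = sps.norm.cdf(z)
        cesd_pre = _ppf_trunc(u[:, 0], arm.cesd_mean, arm.cesd_sd, CESD_MIN, CESD_MAX)
        k10_pre = _ppf_trunc(u[:, 1], arm.k10_mean, arm.k10_sd, K10_MIN, K10_MAX)
        change = rng.normal(arm.change_mean, arm.change_sd, size=arm.n)
        cesd_post = np.clip(cesd_pre - change, CESD_MIN, CESD_MAX)
        slope = rho * arm.k10_sd / arm.cesd_sd if arm.cesd_sd > 0 else 0.0
        k10_noise_sd = arm.k10_sd * np.sqrt(max(0.0, 1.0 - rho**2))
        k10_post = np.clip(
            k10_pre - slope * change + rng.normal(0.0, k10_noise_sd, size=arm.n),
            K10_MIN, K10_MAX,
        )
        completer = rng.random(arm.n) < arm.retention
        for i in range(arm.n):
            records.append(
                ParticipantRecord(
                    id=f"{arm_name[:3]}-{i + 1:04d}",
                    arm=arm_name,
                    cesd_pre=float(cesd_pre[i]),
                    k10_pre=float(k10_pre[i]),
                    cesd_post=float(cesd_post[i]) if completer[i] else None,
                    k10_post=float(k10_post[i]) if completer[i] else None,
                    completer=bool(completer[i]),
                )
            )
    return records


def _ppf_trunc(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    if sd == 0:
        return np.full(u.shape, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mean, scale=sd)


@dataclass(frozen=True)
class FixtureSpec:
    """A pre/post descriptive-matrix pair for one arm (equal n)."""

    pre: DescriptiveMatrix
    post: DescriptiveMatrix

    def __post_init__(self) -> None:
        if self.pre.n != self.post.n:
            raise ValueError(
                f"pre (n={self.pre.n}) and post (n={self.post.n}) matrices must "
                "cover the same completer set"
            )
        if self.pre.arm != self.post.arm:
            raise ValueError("pre and post matrices belong to different arms")


def generate_from_matrix(
    spec: FixtureSpec,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    id_prefix: Optional[str] = None,
) -> list[ParticipantRecord]:
    """Regenerate participant records from per-timepoint state counts.

    Each participant receives the interval-midpoint (CES-D, K10) pair of an
    assigned state at each timepoint; pre and post state lists are expanded
    in state order and paired index-wise (greedy).  Re-classification of
    the output reproduces both input matrices exactly.
    """
    prefix = id_prefix or spec.pre.arm[:3]

    def expand(matrix: DescriptiveMatrix) -> list[HealthState]:
        out: list[HealthState] = []
        for state in sorted(matrix.counts):
            out.extend([state] * int(matrix.counts[state]))
        return out

    pre_states, post_states = expand(spec.pre), expand(spec.post)
    records = []
    for i, (s_pre, s_post) in enumerate(zip(pre_states, post_states), start=1):
        cesd_pre, k10_pre = scheme.representative_scores(s_pre)
        cesd_post, k10_post = scheme.representative_scores(s_post)
        records.append(
            ParticipantRecord(
                id=f"{prefix}-{i:04d}",
                arm=spec.pre.arm,
                cesd_pre=cesd_pre,
                k10_pre=k10_pre,
                cesd_post=cesd_post,
                k10_post=k10_post,
                completer=True,
            )
        )
    return records
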