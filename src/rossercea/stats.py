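"""Change-score contrasts and Hedges' g between-group effect sizes.

Descriptive only: the downstream economics consume utility changes, not
p-values, so no hypothesis testing is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ChangeContrast", "EffectSize", "change_contrast", "hedges_g"]


@dataclass(frozen=True)
class ChangeContrast:
    """Mean and SD of paired (pre - post) differences; positive = improvement."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a contrast needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def change_contrast(pre_scores: Sequence[float], post_scores: Sequence[float]) -> ChangeContrast:
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"paired score lists differ in length: {pre.size} vs {post.size}")
    if pre.size < 2:
        raise ValueError("a contrast needs at least 2 pairs")
    diff = pre - post
    return ChangeContrast(mean=float(diff.mean()), sd=float(diff.std(ddof=1)), n=int(pre.size))


@dataclass(frozen=True)
class EffectSize:
    g: float
    se: float


def hedges_g(a: ChangeContrast, b: ChangeContrast) -> EffectSize:
    """Hedges' unbiased standardized mean difference between two contrasts.

    g = J x (mean_a - mean_b) / s_pooled, with the pooled SD over both
    groups and small-sample correction J = 1 - 3/(4N - 9), N = n_a + n_b.
    The standard error uses the usual large-sample approximation
    sqrt(N/(n_a n_b) + g^2/(2N)).
    """
    n_a, n_b = a.n, b.n
    pooled_var = ((n_a - 1) * a.sd**2 + (n_b - 1) * b.sd**2) / (n_a + n_b - 2)
    if pooled_var <= 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    big_n = n_a + n_b
    j = 1.0 - 3.0 / (4.0 * big_n - 9.0)
    g = j * (a.mean - b.mean) / math.sqrt(pooled_var)
    se = math.sqrt(big_n / (n_a * n_b) + g**2 / (2.0 * big_n))
    return EffectSize(g=g, se=se)
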