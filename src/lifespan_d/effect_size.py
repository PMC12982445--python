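"""Core effect-size statistics for male/female comparisons.

The central statistic is Cohen's d computed with an equal-weight pooled
standard deviation,

    d = (x̄_M − x̄_F) / sqrt((SD_M² + SD_F²) / 2),

positive when the male mean is larger (females are the reference group).
The equal-weight denominator — the root-mean-square of the two group SDs
rather than the sample-size-weighted pooled SD — is deliberate: growth-chart
sources publish per-age moments without per-age counts, so an n-weighted
denominator is not generally computable. Companion quantities (the raw mean
difference and the pooled SD itself) are carried alongside d because a change
in d can be driven by either the numerator or the denominator.

Also provided: the standard large-sample sampling variance of d, and the
probability-of-superiority transform Φ(d/√2) expressed as a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr

from .errors import (
    DegenerateVarianceError,
    DomainError,
    InsufficientSampleError,
)

__all__ = [
    "MomentPair",
    "EffectResult",
    "pooled_sd",
    "cohens_d",
    "d_sampling_variance",
    "superiority_accuracy",
]


@dataclass(frozen=True)
class MomentPair:
    """Per-sex (mean, SD) of one metric at one age epoch.

    Counts default to 0, meaning "unknown" — chart sources publish moments
    without per-epoch sample sizes.
    """

    mean_m: float
    mean_f: float
    sd_m: float
    sd_f: float
    n_m: int = 0
    n_f: int = 0

    def __post_init__(self) -> None:
        if self.sd_m < 0 or self.sd_f < 0:
            raise DomainError(
                f"standard deviations must be >= 0, got ({self.sd_m}, {self.sd_f})"
            )
        for name in ("n_m", "n_f"):
            n = getattr(self, name)
            if n != int(n) or n < 0:
                raise DomainError(f"{name} must be a non-negative integer, got {n!r}")


@dataclass(frozen=True)
class EffectResult:
    """Cohen's d with its numerator and denominator, and optionally var(d)."""

    d: float
    mean_diff: float
    pooled_sd: float
    var_d: float | None = None


def pooled_sd(sd_m: float, sd_f: float) -> float:
    """Equal-weight pooled SD: sqrt((sd_m² + sd_f²) / 2).

    Symmetric in its arguments; ``pooled_sd(s, s) == s``.

    Raises
    ------
    DomainError
        If either SD is negative.
    DegenerateVarianceError
        If both SDs are zero (d would be undefined).
    """
    if sd_m < 0 or sd_f < 0:
        raise DomainError(f"standard deviations must be >= 0, got ({sd_m}, {sd_f})")
    if sd_m == 0 and sd_f == 0:
        raise DegenerateVarianceError("both group SDs are zero; d is undefined")
    return math.sqrt((sd_m * sd_m + sd_f * sd_f) / 2.0)


def cohens_d(m: MomentPair) -> EffectResult:
    """Cohen's d for a male/female moment pair, male minus female.

    Returns an :class:`EffectResult` whose ``var_d`` is populated from
    :func:`d_sampling_variance` when both counts are known (>= 2), else None.
    """
    sd = pooled_sd(m.sd_m, m.sd_f)
    diff = m.mean_m - m.mean_f
    d = diff / sd
    var = None
    if m.n_m >= 2 and m.n_f >= 2:
        var = d_sampling_variance(d, m.n_m, m.n_f)
    return EffectResult(d=d, mean_diff=diff, pooled_sd=sd, var_d=var)


def d_sampling_variance(d: float, n_m: int, n_f: int) -> float:
    """Large-sample approximation of var(d̂) for two independent groups.

    var(d̂) ≈ (n_m + n_f)/(n_m·n_f) + d²/(2·(n_m + n_f)).
    """
    if n_m < 2 or n_f < 2:
        raise InsufficientSampleError(
            f"need at least 2 observations per group, got ({n_m}, {n_f})"
        )
    n = n_m + n_f
    return n / (n_m * n_f) + d * d / (2.0 * n)


def superiority_accuracy(d: float) -> float:
    """Probability of superiority implied by d, as a percentage.

    For two unit-variance normal distributions separated by ``d``, the
    probability that a random draw from the higher-mean group exceeds an
    independent draw from the other group is Φ(d/√2); this is returned
    on a 0–100 scale.  It is sometimes quoted as a "classification
    accuracy" implied by an effect size (e.g. d = 2.13 → ≈ 93.4%).

    Strictly increasing in d; maps d = 0 to 50.0 and −d to 100 − value.
    """
    if not math.isfinite(d):
        raise DomainError(f"d must be finite, got {d!r}")
    return 100.0 * float(ndtr(d / math.sqrt(2.0)))
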