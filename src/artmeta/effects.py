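"""Standardized mean differences (Hedges' d) from the source statistics
reported in primary studies.

Every converter returns an :class:`EffectSize` carrying the small-sample
corrected d, its large-sample sampling variance

    var(d) = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)),

and bookkeeping metadata.  The Hedges correction factor is

    J = 1 - 3 / (4 * df - 1),  df = n1 + n2 - 2,

applied to the uncorrected standardized difference before the variance is
evaluated.  Signs follow the sperm-competition convention: positive when the
tactic facing the higher sperm-competition risk (or lower pre-mating
investment) shows the larger trait value; :func:`apply_direction` enforces
this given a per-tactic-pair rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

__all__ = [
    "GroupSummary",
    "EffectSize",
    "DirectionRule",
    "hedges_j",
    "hedges_d_from_summary",
    "d_from_t",
    "d_from_paired_t",
    "d_from_mwu",
    "d_from_partial_eta2",
    "apply_direction",
    "directionless_zero",
    "sd_from_se",
]

TRAIT_CATEGORIES = ("testes_size", "sperm_quantity", "sperm_trait")


@dataclass(frozen=True)
class GroupSummary:
    """Per-tactic summary statistics: sample size, mean, SD (trait units)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class DirectionRule:
    """Ordered tactic pair; the second label is the tactic expected to invest
    more post-mating (e.g. ('guarder', 'sneaker'): sneaker > guarder positive).
    """

    low_tactic: str
    high_tactic: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.low_tactic == self.high_tactic:
            raise ValueError("direction rule needs two distinct tactic labels")


@dataclass
class EffectSize:
    """One standardized mean difference with sampling variance and grouping IDs."""

    d: float
    var: float
    species: str = ""
    study_id: str = ""
    experiment_id: str = ""
    observation_id: str = ""
    trait_category: str = ""
    measurement: str = ""
    directionless: bool = False
    conversion: str = ""
    moderators: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValueError(f"sampling variance must be > 0, got {self.var}")
        if self.trait_category and self.trait_category not in TRAIT_CATEGORIES:
            raise ValueError(
                f"trait_category must be one of {TRAIT_CATEGORIES}, "
                f"got {self.trait_category!r}"
            )
        freq = self.moderators.get("sneaker_freq")
        if freq is not None and not (0.0 <= float(freq) <= 1.0):
            raise ValueError(f"sneaker frequency must lie in [0, 1], got {freq}")

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


def hedges_j(df: float) -> float:
    """Small-sample correction factor J = 1 - 3/(4 df - 1)."""
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _d_variance(d: float, n1: int, n2: int) -> float:
    return (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))


def _validate_ns(n1: int, n2: int) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both group sizes must be >= 2, got ({n1}, {n2})")


def sd_from_se(se: float, n: int) -> float:
    """Convert a reported standard error of the mean back to an SD."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return se * math.sqrt(n)


def hedges_d_from_summary(g_high: GroupSummary, g_low: GroupSummary, **meta: Any) -> EffectSize:
    """Hedges' d from two group summaries; positive when g_high's mean is larger.

    Pooled SD uses the usual (n-1)-weighted formula; an exactly zero pooled SD
    with unequal means makes the effect undefined.
    """
    n1, n2 = g_high.n, g_low.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g_high.sd**2 + (n2 - 1) * g_low.sd**2) / df
    diff = g_high.mean - g_low.mean
    if sp2 == 0.0:
        if diff != 0.0:
            raise ValueError("pooled SD is zero with unequal means: effect undefined")
        d = 0.0
    else:
        d = hedges_j(df) * diff / math.sqrt(sp2)
    return EffectSize(d=d, var=_d_variance(d, n1, n2), conversion="summary", **meta)


def d_from_t(t: float, n1: int, n2: int, **meta: Any) -> EffectSize:
    """Hedges' d from a two-sample t statistic."""
    _validate_ns(n1, n2)
    d = hedges_j(n1 + n2 - 2) * t * math.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectSize(d=d, var=_d_variance(d, n1, n2), conversion="t", **meta)


def d_from_paired_t(t: float, n_pairs: int, **meta: Any) -> EffectSize:
    """d from a paired t statistic when the pairwise correlation is unreported.

    Falls back to d = t/sqrt(n) with var = 1/n + d^2/(2n); rows carry the
    conversion tag ``paired_t`` so sensitivity analyses can drop them.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    d = t / math.sqrt(n_pairs)
    var = 1.0 / n_pairs + d * d / (2.0 * n_pairs)
    return EffectSize(d=d, var=var, conversion="paired_t", **meta)


def d_from_mwu(u: float, n1: int, n2: int, **meta: Any) -> EffectSize:
    """Hedges' d from a Mann-Whitney U via the normal approximation.

    Chain: U -> z (no continuity correction) -> point-biserial r -> Cohen's d
    -> Hedges correction.  Recorded in the ``conversion`` tag.
    """
    _validate_ns(n1, n2)
    if not (0 <= u <= n1 * n2):
        raise ValueError(f"U must lie in [0, {n1 * n2}], got {u}")
    z = (u - n1 * n2 / 2.0) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    r = z / math.sqrt(n1 + n2)
    if abs(r) >= 1.0:
        raise ValueError("normal approximation gives |r| >= 1; U too extreme")
    d = hedges_j(n1 + n2 - 2) * 2.0 * r / math.sqrt(1.0 - r * r)
    return EffectSize(d=d, var=_d_variance(d, n1, n2), conversion="mwu", **meta)


def d_from_partial_eta2(eta2: float, n1: int, n2: int, sign: int = 1, **meta: Any) -> EffectSize:
    """Hedges' d from a partial eta-squared (e.g. an ANCOVA tactic term).

    eta^2 is unsigned; ``sign`` carries the direction of the adjusted group
    difference.  Cohen's d = 2*sqrt(eta2/(1-eta2)), then the J correction.
    """
    _validate_ns(n1, n2)
    if not (0.0 <= eta2 < 1.0):
        raise ValueError(f"partial eta-squared must lie in [0, 1), got {eta2}")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    cohen = 2.0 * math.sqrt(eta2 / (1.0 - eta2))
    d = sign * hedges_j(n1 + n2 - 2) * cohen
    return EffectSize(d=d, var=_d_variance(d, n1, n2), conversion="eta2", **meta)


def apply_direction(
    raw: EffectSize, rule: DirectionRule, observed_order: tuple[str, str]
) -> EffectSize:
    """Orient a raw effect to the sperm-competition sign convention.

    ``observed_order`` is the (first, second) tactic order used when the raw d
    was computed as mean(second) - mean(first).  The d is flipped iff that
    order disagrees with the rule's (low, high) expectation.
    """
    first, second = observed_order
    expected = {rule.low_tactic, rule.high_tactic}
    if {first, second} != expected:
        raise ValueError(
            f"observed tactics {observed_order} do not match rule "
            f"({rule.low_tactic!r}, {rule.high_tactic!r})"
        )
    if second == rule.high_tactic:
        return replace(raw)
    return replace(raw, d=-raw.d)


def directionless_zero(n1: int, n2: int, **meta: Any) -> EffectSize:
    """Zero effect for a non-significant result reported without direction.

    Keeps the sample-size part of the variance so the row is still weighted;
    the ``directionless`` flag lets sensitivity analyses drop it.
    """
    _validate_ns(n1, n2)
    meta.pop("directionless", None)
    return EffectSize(
        d=0.0,
        var=(n1 + n2) / (n1 * n2),
        directionless=True,
        conversion="directionless",
        **meta,
    )
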