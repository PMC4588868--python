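"""Fixed-effects inverse-variance meta-analysis of per-cohort effects.

Cohort effects are pooled with weights w_i = 1/SE_i^2; the pooled SE is
1/sqrt(sum w_i) and inference is a two-sided normal z-test.  When a
cohort supplies only an effect and a two-sided p-value (as printed
result tables do), its SE is recovered through the normal quantile,
SE = |effect| / Phi^-1(1 - p/2), which round-trips exactly with the
z-test used for pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CohortEffect:
    """One cohort's effect estimate with its SE and/or two-sided p."""

    label: str
    effect: float
    se: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.se is None and self.p is None:
            raise ValueError(f"cohort {self.label!r}: need se or p")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"cohort {self.label!r}: se must be positive")
        if self.p is not None and not 0 < self.p < 1:
            raise ValueError(f"cohort {self.label!r}: p must be in (0, 1)")

    def resolved_se(self) -> float:
        if self.se is not None:
            return self.se
        return se_from_p(self.effect, self.p)


@dataclass(frozen=True)
class MetaRecord:
    effect: float
    se: float
    z: float
    p: float
    weights: tuple[float, ...]
    labels: tuple[str, ...]
    k: int


def se_from_p(effect: float, p: float) -> float:
    """Standard error implied by an effect and its two-sided normal p."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if effect == 0:
        raise ValueError("cannot recover se for a zero effect")
    z = stats.norm.isf(p / 2.0)
    return abs(effect) / z


def fixed_effects_meta(effects: list[CohortEffect]) -> MetaRecord:
    """Pool cohort effects: sum(w_i e_i)/sum(w_i), w_i = 1/se_i^2."""
    if not effects:
        raise ValueError("need at least one cohort")
    e = np.array([c.effect for c in effects], float)
    se = np.array([c.resolved_se() for c in effects], float)
    w = 1.0 / se**2
    pooled = float((w * e).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled / pooled_se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return MetaRecord(
        effect=pooled,
        se=pooled_se,
        z=float(z),
        p=p,
        weights=tuple(w),
        labels=tuple(c.label for c in effects),
        k=len(effects),
    )


def meta_mediation(records) -> MetaRecord:
    """Pool mediated effects (delta = beta_c - beta_c') across cohorts.

    ``records`` is a list of :class:`CohortEffect` or of
    ``(label, delta, sobel_p)`` tuples; SEs are recovered from the Sobel
    p-values when not supplied directly.
    """
    effects = [
        r if isinstance(r, CohortEffect) else CohortEffect(r[0], r[1], p=r[2])
        for r in records
    ]
    return fixed_effects_meta(effects)


def mediation_confirmed(
    replication_p: float, joint_p: float, alpha: float = 0.05
) -> bool:
    """Confirmation rule: two-sided p < alpha in both replication and joint meta."""
    return replication_p < alpha and joint_p < alpha


def mediation_fraction_of_total(
    pooled_delta: float, pooled_total_effect: float
) -> float:
    """Pooled mediated effect as a fraction of the pooled total effect."""
    if pooled_total_effect == 0:
        raise ValueError("pooled total effect is zero")
    return pooled_delta / pooled_total_effect


def cochran_q(effects: list[CohortEffect]) -> tuple[float, float]:
    """Optional heterogeneity statistic: Q and its chi-square p (df = k-1)."""
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least two cohorts")
    e = np.array([c.effect for c in effects], float)
    w = np.array([1.0 / c.resolved_se() ** 2 for c in effects], float)
    pooled = (w * e).sum() / w.sum()
    q = float((w * (e - pooled) ** 2).sum())
    p = float(stats.chi2.sf(q, len(effects) - 1))
    return q, p
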