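"""Fixed-effect inverse-variance meta-analysis of case-control and TDT
effects.

A TDT result is converted to an odds-ratio scale effect with
``log OR = ln(T/U)`` and ``SE = sqrt(1/T + 1/U)``; the case-control effect
uses the logistic-regression coefficient and its standard error.  Effects
are pooled with weights proportional to 1/SE².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = ["EffectEstimate", "MetaResult", "tdt_to_effect", "effect_from_or_ci",
           "pool_effects", "pool"]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    source: str  # "case_control" | "tdt" | free-form
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")
        if not math.isfinite(self.log_or):
            raise ValueError("log odds ratio must be finite")


@dataclass(frozen=True)
class MetaResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    log_or: float
    se: float
    weights: tuple[float, ...]
    q: float | None = None  # Cochran's Q, if requested

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must contain the pooled OR")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def tdt_to_effect(
    transmitted: int, untransmitted: int, *, continuity: bool = False
) -> EffectEstimate:
    """TDT transmission counts as a log-odds-ratio effect.

    ``log OR = ln(T/U)``, ``SE = sqrt(1/T + 1/U)``.  Zero counts raise
    unless ``continuity`` adds 0.5 to both (off by default).
    """
    t, u = float(transmitted), float(untransmitted)
    if t < 0 or u < 0:
        raise ValueError("transmission counts must be non-negative")
    if t == 0 or u == 0:
        if not continuity:
            raise ValueError(
                "T and U must both be positive; pass continuity=True to add "
                "0.5 to both counts"
            )
        t, u = t + 0.5, u + 0.5
    return EffectEstimate("tdt", math.log(t / u), math.sqrt(1.0 / t + 1.0 / u))


def effect_from_or_ci(
    odds_ratio: float, ci_low: float, ci_high: float, source: str = "case_control"
) -> EffectEstimate:
    """Back-compute a log-OR effect from a reported OR with 95% CI."""
    if not 0 < ci_low <= odds_ratio <= ci_high:
        raise ValueError("need 0 < CI low <= OR <= CI high")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z95)
    return EffectEstimate(source, math.log(odds_ratio), se)


def pool_effects(
    effects: Sequence[EffectEstimate], *, cochran_q: bool = False
) -> MetaResult:
    """Generic inverse-variance fixed-effect pooling."""
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    if len(effects) == 1:
        warnings.warn("pooling a single effect returns it unchanged", stacklevel=2)
    w = [1.0 / (e.se * e.se) for e in effects]
    total = sum(w)
    log_or = sum(wi * e.log_or for wi, e in zip(w, effects)) / total
    se = 1.0 / math.sqrt(total)
    z = log_or / se
    q = None
    if cochran_q:
        q = sum(wi * (e.log_or - log_or) ** 2 for wi, e in zip(w, effects))
    return MetaResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        z=z,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        log_or=log_or,
        se=se,
        weights=tuple(wi / total for wi in w),
        q=q,
    )


pool = pool_effects
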