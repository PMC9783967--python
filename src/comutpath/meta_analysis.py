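"""Random-effects meta-analysis of per-cohort treatment effects.

Pools hazard ratios (OS/PFS) or risk ratios (ORR) across immunotherapy
cohorts with the inverse-variance random-effects model, DerSimonian–Laird
τ² estimator, and Cochran's Q / I² heterogeneity statistics. Standard
errors can be recovered from printed 95% confidence intervals, so a forest
plot can be rebuilt from literature-style inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortEffect",
    "MetaResult",
    "effect_from_counts",
    "effect_from_ci",
    "pool_random_effects",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class CohortEffect:
    """One cohort's effect estimate (HR or RR) with its 95% CI."""

    cohort: str
    effect_type: str  # "HR" | "RR"
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.effect_type not in ("HR", "RR"):
            raise ValueError("effect_type must be HR or RR")
        if not (0 < self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"{self.cohort}: require 0 < ci_low <= estimate <= ci_high"
            )

    @property
    def log_estimate(self) -> float:
        return math.log(self.estimate)

    @property
    def log_se(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * _Z95)


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    effect_type: str
    pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    q: float
    df: int
    tau2: float
    i2: float  # percent
    p_heterogeneity: float
    weights: pd.Series  # normalized RE weights per cohort
    rows: pd.DataFrame  # per-cohort estimate/CI/weight for forest output

    @property
    def consistent(self) -> bool:
        """Study-consistency flag: P_het > 0.1 and I² < 50%."""
        return self.p_heterogeneity > 0.1 and self.i2 < 50.0

    def forest_frame(self) -> pd.DataFrame:
        pooled_row = pd.DataFrame(
            {
                "estimate": [self.pooled],
                "ci_low": [self.ci_low],
                "ci_high": [self.ci_high],
                "weight": [1.0],
            },
            index=["pooled"],
        )
        return pd.concat([self.rows, pooled_row])


def effect_from_counts(
    cohort: str,
    responders_pos: int,
    total_pos: int,
    responders_neg: int,
    total_neg: int,
) -> CohortEffect:
    """Risk ratio from arm counts: RR = (a/n1)/(c/n2).

    Zero cells get the conventional 0.5 continuity correction (applied to
    every cell of the affected cohort); a zero total in either arm is an
    error. log-SE = sqrt(1/a − 1/n1 + 1/c − 1/n2).
    """
    if total_pos <= 0 or total_neg <= 0:
        raise ValueError("zero total in an arm")
    a, n1, c, n2 = responders_pos, total_pos, responders_neg, total_neg
    if min(a, n1 - a, c, n2 - c) < 0:
        raise ValueError("responders exceed totals or are negative")
    if a == 0 or c == 0 or a == n1 or c == n2:
        a, c = a + 0.5, c + 0.5
        n1, n2 = n1 + 1.0, n2 + 1.0
    rr = (a / n1) / (c / n2)
    log_se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    log_rr = math.log(rr)
    return CohortEffect(
        cohort=cohort,
        effect_type="RR",
        estimate=rr,
        ci_low=math.exp(log_rr - _Z95 * log_se),
        ci_high=math.exp(log_rr + _Z95 * log_se),
    )


def effect_from_ci(
    cohort: str, effect_type: str, estimate: float, ci_low: float, ci_high: float
) -> CohortEffect:
    """Wrap a printed estimate + 95% CI (SE recovered from the CI width)."""
    return CohortEffect(cohort, effect_type, estimate, ci_low, ci_high)


def pool_random_effects(
    effects: Sequence[CohortEffect],
    force_fixed: bool = False,
) -> MetaResult:
    """DerSimonian–Laird random-effects pooling on the log scale.

    Fixed-effect weights wᵢ = 1/SEᵢ² give Cochran's Q; τ² = max(0,
    (Q − df)/(Σw − Σw²/Σw)); random-effects weights 1/(SEᵢ² + τ²). The
    pooled CI uses normal quantiles. ``force_fixed`` pins τ² = 0 (the
    fixed-effect model), used for the algebraic cross-check. A single
    effect passes through with a warning and no heterogeneity statistics.
    """
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    types = {e.effect_type for e in effects}
    if len(types) > 1:
        raise ValueError(f"mixed effect types {types}")
    effect_type = types.pop()
    names = [e.cohort for e in effects]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cohort names")
    y = np.array([e.log_estimate for e in effects])
    se = np.array([e.log_se for e in effects])
    rows = pd.DataFrame(
        {
            "estimate": [e.estimate for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
        },
        index=names,
    )
    if len(effects) == 1:
        warnings.warn("single effect: passthrough, no heterogeneity statistics", stacklevel=2)
        e = effects[0]
        z = abs(e.log_estimate) / e.log_se if e.log_se > 0 else np.inf
        rows["weight"] = [1.0]
        return MetaResult(
            effect_type=effect_type,
            pooled=e.estimate,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            p_value=float(2 * stats.norm.sf(z)),
            q=np.nan,
            df=0,
            tau2=np.nan,
            i2=np.nan,
            p_heterogeneity=np.nan,
            weights=pd.Series([1.0], index=names),
            rows=rows,
        )
    w = 1.0 / se**2
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    df = len(effects) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = 0.0 if force_fixed else max(0.0, (q - df) / denom)
    w_re = 1.0 / (se**2 + tau2)
    pooled_log = float(np.sum(w_re * y) / np.sum(w_re))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_re)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df))
    z = abs(pooled_log) / pooled_se
    weights = pd.Series(w_re / w_re.sum(), index=names)
    rows["weight"] = weights
    return MetaResult(
        effect_type=effect_type,
        pooled=math.exp(pooled_log),
        ci_low=math.exp(pooled_log - _Z95 * pooled_se),
        ci_high=math.exp(pooled_log + _Z95 * pooled_se),
        p_value=float(2 * stats.norm.sf(z)),
        q=q,
        df=df,
        tau2=tau2,
        i2=i2,
        p_heterogeneity=p_het,
        weights=weights,
        rows=rows,
    )
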