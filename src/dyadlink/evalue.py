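"""E-value sensitivity analysis for unmeasured confounding.

The E-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both exposure and
outcome — above and beyond the measured covariates — to explain away an
observed effect: E = RR + sqrt(RR (RR - 1)) for RR >= 1, with RR < 1
handled by the reciprocal.

Odds ratios from a common-outcome analysis (prevalence above roughly
15%) are first converted to approximate risk ratios by the square-root
transform RR ~= sqrt(OR); for rare outcomes the OR can stand in for the
RR directly. Both conversions are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = ["EValueResult", "evalue_from_rr", "evalue_for_or"]


@dataclass(frozen=True)
class EValueResult:
    """E-value for a point estimate and for the CI limit closer to the
    null (1 if the interval crosses the null)."""

    rr_used: float
    e_point: float
    e_ci: float
    conversion: str

    def __post_init__(self) -> None:
        assert self.e_point >= self.e_ci >= 1.0 - 1e-12


def evalue_from_rr(rr: float) -> float:
    """E-value of a risk ratio: RR + sqrt(RR (RR - 1)); protective
    effects (RR < 1) use the reciprocal."""
    if not rr > 0:
        raise ValueError("risk ratio must be positive")
    if rr < 1:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))


def evalue_for_or(
    odds_ratio: float,
    ci: Optional[tuple[float, float]] = None,
    outcome_common: bool = True,
) -> EValueResult:
    """E-value for an odds-ratio effect estimate.

    ``outcome_common=True`` (the default here: the analysis outcome has
    ~29% prevalence) applies the square-root OR->RR conversion; with a
    rare outcome the OR is used as the RR. The CI-limit E-value uses the
    limit nearer the null and is 1 when the interval spans 1.
    """
    if not odds_ratio > 0:
        raise ValueError("odds ratio must be positive")
    conv = "sqrt_or" if outcome_common else "or_as_rr"

    def to_rr(x: float) -> float:
        return math.sqrt(x) if outcome_common else x

    rr = to_rr(odds_ratio)
    e_point = evalue_from_rr(rr)
    e_ci = 1.0
    if ci is not None:
        lo, hi = ci
        if not (lo <= odds_ratio <= hi):
            raise ValueError("CI must bracket the odds ratio")
        if lo > 1.0:
            e_ci = evalue_from_rr(to_rr(lo))
        elif hi < 1.0:
            e_ci = evalue_from_rr(to_rr(hi))
        # else: interval spans the null -> 1
    return EValueResult(rr_used=rr, e_point=e_point, e_ci=e_ci, conversion=conv)
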