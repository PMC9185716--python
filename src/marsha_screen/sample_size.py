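"""Sample-size calculation for estimating a screener's sensitivity.

The number of condition-positive cases needed to estimate a sensitivity
(or specificity) ``p`` to within a maximum marginal error ``d`` at two-sided
significance ``alpha`` is

    n_cases = Z^2 * p * (1 - p) / d^2

with Z the standard-normal two-sided quantile (1.96 at alpha = 0.05).  The
total sample size divides the cases by the anticipated condition prevalence.

Rounding conventions are explicit because published worked examples mix them:
cases are rounded up (a fractional case requires another subject), while the
``"paper"`` mode truncates the prevalence-inflated total, matching the
convention seen in applied write-ups (49 / 0.409 = 119.8 -> 119); ``"ceil"``
rounds the total up instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

RoundingMode = Literal["paper", "ceil"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs for the sensitivity-estimation sample-size formula."""

    p_hat: float
    d: float
    prevalence: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p_hat < 1:
            raise ValueError("anticipated sensitivity must be in (0, 1)")
        if not 0 < self.d < 1:
            raise ValueError("marginal error must be in (0, 1)")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def z(self) -> float:
        """Two-sided standard-normal quantile for the chosen alpha."""
        return float(stats.norm.ppf(1 - self.alpha / 2))


def required_cases(spec: SampleSizeSpec) -> int:
    """Condition-positive cases needed: ceil(Z^2 p(1-p) / d^2)."""
    raw = spec.z**2 * spec.p_hat * (1 - spec.p_hat) / spec.d**2
    return math.ceil(raw)


def required_total(spec: SampleSizeSpec, rounding: RoundingMode = "paper") -> int:
    """Total sample size: cases inflated by 1/prevalence.

    ``rounding="paper"`` truncates toward zero; ``"ceil"`` rounds up.
    """
    cases = required_cases(spec)
    raw = cases / spec.prevalence
    if rounding == "paper":
        return math.trunc(raw)
    if rounding == "ceil":
        return math.ceil(raw)
    raise ValueError(f"unknown rounding mode {rounding!r}")
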