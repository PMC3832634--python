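"""Algebra on allometric scaling exponents.

Scaling exponents compose additively on the log scale: if limb MOI is
I = m r**2 and m ∝ M^p, r ∝ M^q, then I ∝ M^(p + 2q). Likewise the
angular acceleration a limb can be given, alpha = sum(f k) / I, scales as
M^(f_exp + k_exp − I_exp). Confidence limits propagate by worst-case
interval arithmetic: the upper limit of a quotient combines upper limits of
the numerator terms with the lower limit of the denominator, and vice
versa. The point estimate therefore always lies inside the propagated
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "ExponentEstimate",
    "AccelerationScaling",
    "compose_moi_exponent",
    "angular_acceleration_exponent",
    "acceleration_limits",
]


@dataclass(frozen=True)
class ExponentEstimate:
    """A scaling exponent with an optional 95% confidence interval.

    ``source`` tags where the number came from: ``fitted`` (an RMA fit from
    this package), ``literature`` (a published regression), or
    ``null-model`` (a geometric-similarity prediction).
    """

    value: float
    ci: Optional[Tuple[float, float]] = None
    source: str = "fitted"

    def __post_init__(self) -> None:
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= self.value <= hi):
                raise ValueError(
                    f"CI ({lo}, {hi}) does not bracket the estimate {self.value}"
                )

    def require_ci(self) -> Tuple[float, float]:
        if self.ci is None:
            raise ValueError("a confidence interval is required but missing")
        return self.ci


@dataclass(frozen=True)
class AccelerationScaling:
    """Derived angular-acceleration exponent for one limb with its limits."""

    limb: str
    exponent: float
    limit_lower: float
    limit_upper: float

    def __post_init__(self) -> None:
        if not (self.limit_lower <= self.exponent <= self.limit_upper):
            raise ValueError("point estimate escapes its propagated limits")


def compose_moi_exponent(
    mass_exp: ExponentEstimate, radius_exp: ExponentEstimate
) -> ExponentEstimate:
    """MOI exponent from limb-mass and radius-of-gyration exponents.

    From I = m r**2: the MOI exponent is the mass exponent plus twice the
    radius exponent. When both inputs carry CIs the result's CI is the
    worst-case composition of the bounds.
    """
    value = mass_exp.value + 2.0 * radius_exp.value
    ci = None
    if mass_exp.ci is not None and radius_exp.ci is not None:
        ci = (
            mass_exp.ci[0] + 2.0 * radius_exp.ci[0],
            mass_exp.ci[1] + 2.0 * radius_exp.ci[1],
        )
    return ExponentEstimate(value, ci=ci, source="fitted")


def angular_acceleration_exponent(
    force_exp: float, moment_arm_exp: float, moi_exp: float
) -> float:
    """Exponent of maximal limb angular acceleration against body mass.

    alpha = sum(f k) / I gives exponent f + k − I. Geometric-similarity
    inputs (2/3, 1/3, 5/3) yield −2/3: heavier animals lose angular
    acceleration potential relative to body mass even under isometry.
    """
    return force_exp + moment_arm_exp - moi_exp


def acceleration_limits(
    force: ExponentEstimate,
    arm: ExponentEstimate,
    moi: ExponentEstimate,
    limb: str = "hind",
) -> AccelerationScaling:
    """Worst-case confidence limits on the angular-acceleration exponent.

    The upper limit takes the upper limits of muscle force and moment arm
    with the lower limit of MOI (maximizing acceleration potential); the
    lower limit does the opposite. All three inputs must carry CIs.
    """
    f_lo, f_hi = force.require_ci()
    k_lo, k_hi = arm.require_ci()
    i_lo, i_hi = moi.require_ci()
    point = angular_acceleration_exponent(force.value, arm.value, moi.value)
    upper = f_hi + k_hi - i_lo
    lower = f_lo + k_lo - i_hi
    return AccelerationScaling(
        limb=limb, exponent=point, limit_lower=lower, limit_upper=upper
    )
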