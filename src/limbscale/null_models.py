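"""Geometric-similarity (isometric) null exponents, derived, not hard-coded.

Under geometric similarity, shape is invariant with size: every
characteristic length scales as body mass to the 1/3 and mass-like
quantities scale as body mass to the 1. Every other trait exponent is
composed dimensionally from those two primitives, so the predicted
exponents here are exact rationals produced by arithmetic on
``Fraction(1, 3)`` and ``Fraction(1)`` rather than transcribed decimals.

Compositions:

* length, COM position, radius of gyration — characteristic lengths: 1/3
* limb mass — a mass: 1
* MOI = m r**2 — mass + 2 x length: 5/3
* natural frequency F = (1/2 pi) sqrt(m g d / I) — (mass + length − moi)/2: −1/6
* muscle cross-sectional area — an area: 2/3
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict

__all__ = ["GS_MASS", "GS_LENGTH", "gs_predicted_exponent", "gs_table", "display_exponent"]

#: exponent of body mass for a mass-like trait under geometric similarity
GS_MASS = Fraction(1)
#: exponent of body mass for a characteristic length under geometric similarity
GS_LENGTH = Fraction(1, 3)


def _compositions() -> Dict[str, Fraction]:
    mass = GS_MASS
    length = GS_LENGTH
    moi = mass + 2 * length            # I = m r^2
    freq = (mass + length - moi) / 2   # F ~ sqrt(m d / I)
    return {
        "length": length,
        "mass": mass,
        "com_position": length,
        "moi": moi,
        "radius_of_gyration": length,
        "natural_frequency": freq,
        "muscle_area": 2 * length,     # area ~ length^2
    }


_GS = _compositions()


def gs_predicted_exponent(trait: str) -> Fraction:
    """Exact geometric-similarity exponent for ``trait``.

    Parameters
    ----------
    trait:
        One of ``length``, ``mass``, ``com_position``, ``moi``,
        ``radius_of_gyration``, ``natural_frequency``, ``muscle_area``.

    Returns
    -------
    fractions.Fraction
        The exponent b in trait ∝ (body mass)**b under isometry.
    """
    try:
        return _GS[trait]
    except KeyError:
        raise ValueError(
            f"unknown trait {trait!r}; expected one of {sorted(_GS)}"
        ) from None


def gs_table() -> Dict[str, Fraction]:
    """All geometric-similarity predicted exponents, keyed by trait."""
    return dict(_GS)


def display_exponent(value: Fraction, decimals: int = 2) -> float:
    """Render an exact exponent at the precision used in printed tables.

    5/3 prints as 1.67 and −1/6 as −0.17 at two decimals; full precision
    is kept internally and only rounded here, at display.
    """
    return round(float(value), decimals)
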