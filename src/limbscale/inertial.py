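"""Limb inertial properties from two-scale suspension and pendulum swings.

A dissected limb is clamped to a calibration bar of known mass, COM
position and moment of inertia, and the combination is (1) hung from two
spring scales to locate its centre of mass by static moment balance and
(2) swung about a fixed pivot to obtain its natural period, from which the
compound-pendulum relation

    I_combo = (m_limb + m_bar) * g * d_combo * (T / 2 pi)**2

gives the combined moment of inertia about the pivot. Subtracting the
bar's known contributions isolates the limb's COM position and MOI, and
from those the radius of gyration r = sqrt(I/m) and the pendular natural
frequency F = (1/2 pi) sqrt(m g d / I).

All computation is in SI units (kg, m, s, Hz). The small-angle period
formula is used by default, matching release amplitudes of a few tens of
degrees as used in practice; an optional large-amplitude correction
(first two terms of the elliptic-integral series) is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = [
    "BarSpec",
    "PendulumTrial",
    "InertialProperties",
    "DegenerateInputError",
    "com_from_two_scales",
    "limb_com",
    "moi_from_period",
    "radius_of_gyration",
    "natural_frequency",
    "compute_inertial_properties",
]

G_DEFAULT = 9.81


class DegenerateInputError(ValueError):
    """Raised when a measurement record cannot support the computation."""


@dataclass(frozen=True)
class BarSpec:
    """Calibration bar with known inertial properties about the pivot."""

    mass: float
    com_distance_from_pivot: float
    moi_about_pivot: float

    def __post_init__(self) -> None:
        if self.mass < 0 or self.com_distance_from_pivot < 0 or self.moi_about_pivot < 0:
            raise ValueError("bar properties must be non-negative")
        # parallel-axis lower bound: a rigid body's MOI about the pivot is at
        # least that of a point mass at its COM
        min_moi = self.mass * self.com_distance_from_pivot**2
        if self.moi_about_pivot < min_moi * (1 - 1e-9):
            raise ValueError(
                f"bar MOI {self.moi_about_pivot} below point-mass bound {min_moi}"
            )

    @classmethod
    def massless(cls) -> "BarSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PendulumTrial:
    """Raw measurements for one limb-bar combination.

    ``scale_reading_near``/``scale_reading_far`` are the two suspension
    readings (any force unit, used only as a ratio plus a consistency
    check), taken at supports ``near_support_offset_from_pivot`` and
    ``near_support_offset_from_pivot + support_separation`` metres from
    the pivot along the limb axis.
    """

    limb_mass: float
    bar: BarSpec
    scale_reading_near: float
    scale_reading_far: float
    support_separation: float
    near_support_offset_from_pivot: float
    oscillation_period: float
    gravity: float = G_DEFAULT

    def __post_init__(self) -> None:
        if self.limb_mass <= 0:
            raise ValueError("limb_mass must be positive")
        if self.support_separation <= 0:
            raise ValueError("support_separation must be positive")
        if self.oscillation_period <= 0:
            raise ValueError("oscillation_period must be positive")
        if self.scale_reading_near < 0 or self.scale_reading_far < 0:
            raise ValueError("scale readings must be non-negative")
        if self.scale_reading_near == 0 and self.scale_reading_far == 0:
            raise DegenerateInputError("both scale readings are zero")

    @property
    def combo_mass(self) -> float:
        return self.limb_mass + self.bar.mass


@dataclass
class InertialProperties:
    """Length-independent inertial properties of one limb about its pivot."""

    length: float
    mass: float
    com_position: float
    moi: float
    radius_of_gyration: float
    natural_frequency: float
    pivot: Optional[str] = None  # e.g. 'scapular spine' / 'hip joint'
    warnings: List[str] = field(default_factory=list)


def com_from_two_scales(trial: PendulumTrial, weight_tolerance: float = 0.05) -> float:
    """COM position of the limb-bar combination from the two scale readings.

    Static moment balance about the near support gives

        x_combo = near_offset + separation * R_far / (R_near + R_far)

    If the readings are in weight units their sum is checked against the
    known combined weight to within ``weight_tolerance`` (relative); pass
    ``weight_tolerance=None`` to skip when readings are relative only.
    """
    r_near, r_far = trial.scale_reading_near, trial.scale_reading_far
    total = r_near + r_far
    if total <= 0:
        raise DegenerateInputError("both scale readings are zero")
    if weight_tolerance is not None:
        expected = trial.combo_mass * trial.gravity
        if abs(total - expected) > weight_tolerance * expected:
            raise ValueError(
                f"scale readings sum to {total:.4g} but combined weight is "
                f"{expected:.4g} (tolerance {weight_tolerance:.0%})"
            )
    return trial.near_support_offset_from_pivot + trial.support_separation * r_far / total


def limb_com(combo_com: float, trial: PendulumTrial,
             limb_length: Optional[float] = None) -> Tuple[float, List[str]]:
    """Limb COM position by removing the bar from the mass-weighted mean.

    Returns the limb COM distance from the pivot plus any warning messages
    (a COM outside [0, limb length] is flagged, not rejected — noisy
    readings on small limbs can push it slightly out of range).
    """
    warns: List[str] = []
    bar = trial.bar
    d = (trial.combo_mass * combo_com - bar.mass * bar.com_distance_from_pivot) / trial.limb_mass
    if d < 0:
        warns.append(f"limb COM {d:.4g} m is proximal to the pivot")
    if limb_length is not None and d > limb_length * 1.05:
        warns.append(f"limb COM {d:.4g} m exceeds limb length {limb_length:.4g} m")
    return d, warns


def _amplitude_correction(amplitude_rad: float) -> float:
    """Period inflation factor T(theta0)/T0, elliptic series to 2nd order."""
    return 1.0 + amplitude_rad**2 / 16.0 + 11.0 * amplitude_rad**4 / 3072.0


def moi_from_period(trial: PendulumTrial, combo_com: float,
                    amplitude_rad: Optional[float] = None) -> Tuple[float, List[str]]:
    """Limb MOI about the pivot from the measured oscillation period.

    Inverts the small-angle compound-pendulum period and subtracts the
    bar's known MOI. If ``amplitude_rad`` is given, the measured period is
    first deflated by the large-amplitude correction factor. A negative
    limb MOI after bar subtraction is clamped to zero with a warning.
    """
    warns: List[str] = []
    period = trial.oscillation_period
    if amplitude_rad is not None:
        period = period / _amplitude_correction(amplitude_rad)
    i_combo = trial.combo_mass * trial.gravity * combo_com * (period / (2 * math.pi)) ** 2
    i_limb = i_combo - trial.bar.moi_about_pivot
    if i_limb < 0:
        warns.append(
            f"bar MOI exceeds combined MOI by {-i_limb:.4g} kg m^2; limb MOI clamped to 0"
        )
        i_limb = 0.0
    return i_limb, warns


def radius_of_gyration(mass: float, moi: float) -> float:
    """r = sqrt(I/m): the shape component of MOI."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if moi < 0:
        raise ValueError("MOI must be non-negative")
    return math.sqrt(moi / mass)


def natural_frequency(mass: float, com_position: float, moi: float,
                      gravity: float = G_DEFAULT) -> float:
    """Pendular natural frequency F = (1/2 pi) sqrt(m g d / I), in Hz."""
    if moi <= 0:
        raise ValueError("MOI must be positive for a finite natural frequency")
    if com_position <= 0 or mass <= 0:
        raise ValueError("mass and COM position must be positive")
    return math.sqrt(mass * gravity * com_position / moi) / (2 * math.pi)


def compute_inertial_properties(
    trial: PendulumTrial,
    limb_length: float,
    pivot: Optional[str] = None,
    weight_tolerance: float = 0.05,
    amplitude_rad: Optional[float] = None,
) -> InertialProperties:
    """Full pipeline: two-scale COM, pendulum MOI, r and F for one limb.

    Warnings from each stage are collected on the returned record; they
    are emitted as :class:`UserWarning` as well so batch runs surface them.
    """
    if limb_length <= 0:
        raise ValueError("limb_length must be positive")
    combo_com = com_from_two_scales(trial, weight_tolerance=weight_tolerance)
    d, w1 = limb_com(combo_com, trial, limb_length=limb_length)
    moi, w2 = moi_from_period(trial, combo_com, amplitude_rad=amplitude_rad)
    warns = w1 + w2
    r = radius_of_gyration(trial.limb_mass, moi)
    if moi > 0 and d > 0:
        freq = natural_frequency(trial.limb_mass, d, moi, gravity=trial.gravity)
    else:
        freq = float("nan")
        warns.append("natural frequency undefined (zero MOI or non-positive COM)")
    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return InertialProperties(
        length=limb_length,
        mass=trial.limb_mass,
        com_position=d,
        moi=moi,
        radius_of_gyration=r,
        natural_frequency=freq,
        pivot=pivot,
        warnings=warns,
    )
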