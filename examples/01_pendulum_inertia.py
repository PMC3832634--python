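"""Recover a limb's inertial properties from raw pendulum measurements.

A limb strapped to a rigid bar is weighed on two scales (to locate the
center of mass by moment balance) and swung as a compound pendulum (to
get the moment of inertia from the small-angle period). This script
synthesizes one such trial from known ground truth, then runs it back
through the estimation pipeline to show every derived quantity.
"""

import math

from limbscale import BarSpec, compute_inertial_properties, make_pendulum_trial

# Ground truth for a medium-sized forelimb: 2.4 kg, COM 28 cm below the
# pivot, MOI 1.35x the point-mass bound m d^2.
MASS, COM, MOI = 2.4, 0.28, 2.4 * 0.28**2 * 1.35

# The mounting bar is not massless; its own properties are subtracted.
bar = BarSpec(mass=0.6, com_distance_from_pivot=0.22,
              moi_about_pivot=0.6 * 0.22**2 * 1.4)

trial = make_pendulum_trial(MASS, COM, MOI, bar=bar)
print("Synthesized raw measurements:")
print(f"  scale readings (N): near {trial.scale_reading_near:.3f}, "
      f"far {trial.scale_reading_far:.3f}")
print(f"  support separation (m): {trial.support_separation:.3f}")
print(f"  oscillation period (s): {trial.oscillation_period:.4f}")

props = compute_inertial_properties(trial, limb_length=0.55)
print("\nRecovered inertial properties:")
print(f"  mass               {props.mass:.3f} kg   (truth {MASS})")
print(f"  COM position       {props.com_position:.4f} m  (truth {COM})")
print(f"  moment of inertia  {props.moi:.5f} kg m^2 (truth {MOI:.5f})")
print(f"  radius of gyration {props.radius_of_gyration:.4f} m "
      f"(truth {math.sqrt(MOI / MASS):.4f})")
print(f"  natural frequency  {props.natural_frequency:.4f} Hz")
if props.warnings:
    print("  warnings:", "; ".join(props.warnings))
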