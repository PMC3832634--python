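"""What limb inertia scaling implies for angular acceleration capacity.

Maximum angular acceleration of a limb scales as muscle force x moment
arm / moment of inertia. Composing the scaling exponents of those three
quantities (alpha = f + k - i) therefore predicts how swing acceleration
capacity changes with body size, with worst-case confidence limits from
interval arithmetic on the component confidence intervals.
"""

from limbscale import (
    ExponentEstimate,
    acceleration_limits,
    compose_moi_exponent,
    constants,
    gs_table,
)

# Under geometric similarity the composition is exact rational algebra:
gs = gs_table()
alpha_iso = gs["muscle_area"] + gs["length"] - gs["moi"]
print(f"isometric null: alpha ~ M^{alpha_iso} = M^{float(alpha_iso):.2f}")

# The MOI exponent itself decomposes through I = m r^2: the limb-mass
# exponent plus twice the radius-of-gyration exponent.
moi_fore = compose_moi_exponent(
    ExponentEstimate(constants.MASS_FORELIMB.value),
    ExponentEstimate(constants.RADIUS_FORELIMB.value),
)
print(f"forelimb MOI exponent from m + 2r: {moi_fore.value:.2f} "
      f"(fitted directly: {constants.MOI_FORELIMB.value:.2f})")

# Empirical composition with worst-case confidence limits.
for limb, force, arm, moi in [
    ("hind", constants.MUSCLE_FORCE, constants.MOMENT_ARM_HINDLIMB,
     constants.MOI_HINDLIMB_LIMITS),
    ("fore", constants.MUSCLE_FORCE_FORELIMB, constants.MOMENT_ARM_FORELIMB,
     constants.MOI_FORELIMB_LIMITS),
]:
    acc = acceleration_limits(force, arm, moi, limb=limb)
    print(f"{limb}limb: alpha ~ M^{acc.exponent:.2f} "
          f"(limits {acc.limit_lower:.2f} to {acc.limit_upper:.2f})")

print("\nAll exponents are negative: bigger mammals swing their limbs with")
print("disproportionately less angular acceleration. The decline is milder")
print("than the isometric -2/3 because above-isometric muscle-force and")
print("moment-arm scaling partly offsets the extra growth in limb MOI.")
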