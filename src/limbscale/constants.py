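"""Versioned literature scaling exponents used in exponent composition.

Peak muscle force and muscle moment-arm exponents come from published
interspecific regressions (Alexander and colleagues' classic muscle
dimension dataset): peak muscle force scales as M^0.80, ankle-extensor
moment arms as M^0.38, and the triceps moment arm as M^0.41, each with the
95% confidence limits reproduced below. They are inputs to the
angular-acceleration composition, never re-estimated here.

The whole-sample limb MOI exponents and confidence limits are the RMA
estimates from the quadrupedal-mammal limb dataset this package models
(forelimb 1.78 with CI 1.68–1.89; hindlimb 1.66 with CI 1.56–1.76), along
with the limb-mass and radius-of-gyration exponents used to compose the
forelimb MOI exponent 1.79 = 1.01 + 2 x 0.39.
"""

from __future__ import annotations

from .exponents import ExponentEstimate

CONSTANTS_VERSION = "2013.1"

#: peak muscle force ∝ M^0.80 (95% CI 0.75–0.85)
MUSCLE_FORCE = ExponentEstimate(0.80, ci=(0.75, 0.85), source="literature")

#: the forelimb composition is printed with a force upper limit of 0.86
#: (rounding of the same source regression); kept verbatim so each limb's
#: published limit row reproduces exactly
MUSCLE_FORCE_FORELIMB = ExponentEstimate(0.80, ci=(0.75, 0.86), source="literature")

#: ankle-extensor moment arm ∝ M^0.38 (95% CI 0.35–0.41) — used for hindlimb
MOMENT_ARM_HINDLIMB = ExponentEstimate(0.38, ci=(0.35, 0.41), source="literature")

#: triceps moment arm ∝ M^0.41 (95% CI 0.38–0.44) — used for forelimb
MOMENT_ARM_FORELIMB = ExponentEstimate(0.41, ci=(0.38, 0.44), source="literature")

#: whole-sample RMA exponent for forelimb MOI against body mass
MOI_FORELIMB = ExponentEstimate(1.78, ci=(1.680, 1.891), source="fitted")

#: whole-sample RMA exponent for hindlimb MOI against body mass
MOI_HINDLIMB = ExponentEstimate(1.66, ci=(1.562, 1.762), source="fitted")

#: whole-sample RMA exponent for forelimb mass against body mass
MASS_FORELIMB = ExponentEstimate(1.01, ci=(0.964, 1.067), source="fitted")

#: whole-sample RMA exponent for forelimb radius of gyration
RADIUS_FORELIMB = ExponentEstimate(0.39, ci=(0.359, 0.426), source="fitted")

#: whole-sample RMA exponent for hindlimb mass against body mass
MASS_HINDLIMB = ExponentEstimate(1.03, ci=(0.970, 1.069), source="fitted")

#: whole-sample RMA exponent for hindlimb radius of gyration
RADIUS_HINDLIMB = ExponentEstimate(0.33, ci=(0.297, 0.366), source="fitted")

#: Table-10-style CI bounds used for the angular-acceleration limits,
#: rounded to the two decimals at which the composition is printed
MOI_FORELIMB_LIMITS = ExponentEstimate(1.78, ci=(1.68, 1.89), source="fitted")
MOI_HINDLIMB_LIMITS = ExponentEstimate(1.66, ci=(1.56, 1.76), source="fitted")
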