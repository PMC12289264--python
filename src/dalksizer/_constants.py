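"""Package-wide numerical and clinical constants.

Every module pulls its defaults from here so that the keratometric index,
punch granularity and tolerance are stated exactly once.
"""

#: Keratometric conversion constant, in D*mm: radius_mm = KINDEX / keratometry_D.
#: 337.5 corresponds to the standard keratometric refractive index n = 1.3375
#: used by clinical keratometers ((1.3375 - 1) * 1000).
KINDEX_DEFAULT: float = 337.5

#: Granularity of commercially available trephine/punch sizes, in mm.
PUNCH_STEP_DEFAULT: float = 0.25

#: Relative floating-point tolerance for internal invariant checks.
REL_TOL: float = 1e-9

#: Clinically validated envelope: the tabulated domain of the recommendation
#: grid.  Inputs outside it are accepted but trigger a warning.
K_TABLE_RANGE = (45.0, 70.0)         # diopters
TREPHINE_TABLE_RANGE = (6.00, 8.00)  # mm

#: Wider plausibility envelope for human corneas; outside it the warning is
#: more emphatic but computation still proceeds (only geometric impossibility
#: is a hard error).
K_PLAUSIBLE_RANGE = (20.0, 90.0)       # diopters
TREPHINE_PLAUSIBLE_RANGE = (4.0, 10.0)  # mm
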