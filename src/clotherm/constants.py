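"""Physical constants and protocol defaults shared across the package.

All quantities are SI unless the name says otherwise (clo is the
conventional clothing-insulation unit, 1 clo = 0.155 m2K/W).
"""

#: m2K/W per clo.
CLO_SI = 0.155

#: Lewis relation (K/Pa) linking dry and evaporative heat-transfer resistance.
LEWIS_RELATION = 16.5e-3

#: Whole-body air-layer (boundary-layer) insulation of the nude manikin, m2K/W.
I_A_NUDE = 0.099

#: Whole-body air-layer evaporative resistance measured with the wetted
#: textile skin alone, m2Pa/W (corrected value).
R_EA_TEXTILE_SKIN = 8.0

#: Manikin surface set-point, degC.
SETPOINT_C = 34.0

#: Relative humidity at the wetted textile skin, % (mean over conditions).
SKIN_RH_DEFAULT = 96.0

#: Floor applied to per-zone mean heat loss (W) before any division; avoids
#: infinities when heavily insulated zones drop to (or below) zero flux.
HEAT_LOSS_FLOOR_W = 0.01

#: Canonical names of the 17 individually controlled manikin zones.
ZONE_NAMES = (
    "head",
    "chest",
    "back",
    "stomach",
    "buttocks",
    "left_upper_arm",
    "right_upper_arm",
    "left_lower_arm",
    "right_lower_arm",
    "left_hand",
    "right_hand",
    "left_thigh",
    "right_thigh",
    "left_calf",
    "right_calf",
    "left_foot",
    "right_foot",
)
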