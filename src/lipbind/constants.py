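"""Physical constants and assay defaults shared across modules.

All defaults can be overridden at call sites; they are collected here so a
pipeline run can log the values actually used.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K = 1.987e-3

#: Bulk water concentration (mol/L) used in the mole-fraction partitioning
#: model. 55.5 M is the standard molarity of pure water at 25 degC.
WATER_MOLARITY_M = 55.5

#: Assay temperature (K); titrations were performed at 25 degC.
DEFAULT_TEMPERATURE_K = 298.15

#: Protein-inhibitor (IP6) dissociation constant, uM.
DEFAULT_KI_UM = 1.8

#: Stopped-flow instrument dead time, seconds.
DEFAULT_DEAD_TIME_S = 1.4e-3

#: Fraction of total bulk lipid accessible on liposome outer leaflets.
ACCESSIBLE_LIPID_FRACTION = 0.5

#: Contact cutoff distances (Angstrom) for basic side-chain anchors.
LYS_CUTOFF_A = 5.0
ARG_CUTOFF_A = 6.3
HIS_CUTOFF_A = 6.1

#: Charge-+1 proton mass (Da), used for fragment-ion m/z.
PROTON_MASS_DA = 1.00727646688
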