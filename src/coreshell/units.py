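"""Physical constants and unit conversions used across the package.

All lengths are nanometres, temperatures kelvin, viscosities Pa·s unless a
name says otherwise.  Conversions are centralized here so that every module
agrees on them.
"""

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23

# 1 µg/µL = 1e-6 g / 1e18 nm³ (1 µL = 1e-6 L = 1e18 nm³)
UG_PER_UL_TO_G_PER_NM3 = 1e-24

NM_TO_M = 1e-9
M_TO_NM = 1e9

# PEG repeat unit (-CH2-CH2-O-) molar mass, g/mol
PEG_REPEAT_G_PER_MOL = 44.05

# stoichiometric defaults for nucleic-acid / PEI mass bookkeeping
MW_PER_PHOSPHATE_G_PER_MOL = 330.0   # average nucleotide residue
MW_PER_NITROGEN_G_PER_MOL = 43.1     # PEI repeat per protonatable nitrogen


def ug_per_ul_to_g_per_nm3(rho: float) -> float:
    """Convert a density in µg/µL to g/nm³."""
    return rho * UG_PER_UL_TO_G_PER_NM3
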