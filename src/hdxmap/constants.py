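"""Physical constants and residue mass tables used across the package.

All masses in Da unless stated otherwise.
"""

#: Monoisotopic mass difference between deuterium and protium (2H - 1H).
DEUTERIUM_MASS_SHIFT = 1.006277

#: Mass added by a BS3 (bis-sulfosuccinimidyl suberate) crosslink between two
#: amines after loss of both NHS leaving groups: the C8H10O2 suberate bridge.
BS3_D0_MASS = 138.06808

#: Mass offset of the d4 (tetra-deuterated) BS3 species relative to d0.
BS3_D4_DELTA = 4 * DEUTERIUM_MASS_SHIFT  # 4.025108

#: Hydrolyzed BS3 mono-link ("dead end"): bridge + H2O.
BS3_DEADEND_MASS = 156.07864

WATER_MONO = 18.010565
WATER_AVERAGE = 18.0153

#: Average residue masses (Expasy), used for SEC-MALS-scale molar masses.
AVERAGE_AA_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Gill & von Hippel molar extinction coefficients at 280 nm (M^-1 cm^-1).
EPSILON_TRP = 5500
EPSILON_TYR = 1490
EPSILON_CYSTINE = 125

AMINO_ACIDS = frozenset(AVERAGE_AA_MASS)
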