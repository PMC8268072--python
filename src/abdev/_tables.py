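"""Embedded constant tables: propensity scales, reference SASA, pKa, radii.

All per-residue scales cover exactly the 20 standard amino acids; the
aggregation module z-scores them over the 20 values before use, so only
the relative ordering of each scale matters downstream.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Chou-Fasman beta-sheet conformational preferences (P_beta).
CHOU_FASMAN_BETA = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

# Chou-Fasman alpha-helix conformational preferences (P_alpha).
CHOU_FASMAN_ALPHA = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

# Formal side-chain charge at pH 7 (His given a fractional +0.1).
CHARGE_AT_PH7 = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE_AT_PH7.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.1})

# Theoretical maximum SASA (A^2) per residue in a Gly-X-Gly tripeptide
# (Tien et al. 2013, theoretical column). Used to normalise absolute
# per-residue SASA into relative exposure.
MAX_SASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# EMBOSS-style ionisable-group pKa values.
DEFAULT_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}

BASIC_GROUPS = frozenset({"Nterm", "H", "K", "R"})
ACIDIC_GROUPS = frozenset({"Cterm", "D", "E", "C", "Y"})

# Van der Waals radii (A) by element for SASA computation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70
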