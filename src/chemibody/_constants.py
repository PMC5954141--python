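"""Bundled physical-constant tables.

Small, frozen reference data used across the package: van-der-Waals radii
for surface-area integration, free-residue reference areas for relative
exposure, isotope masses for mass spectrometry bookkeeping, and ideal
bond geometry for linker extension bounds.
"""

from __future__ import annotations

#: van-der-Waals radii (Å), Bondi (1964) with common biomolecular elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
}

#: Theoretical maximum solvent accessibility (Å²) of residue X in an
#: extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical set).
#: Used as the denominator of relative per-residue exposure.
GXG_REFERENCE_AREA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Monoisotopic masses of the most abundant isotope (Da), CODATA/AME2020.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "P": 30.9737615120,
    "S": 31.9720706990,
    "CL": 34.9688526900,
    "BR": 78.9183376000,
    "I": 126.9044719000,
    "B": 11.0093053645,
    "SE": 79.9165218000,
}

#: Standard atomic weights (Da), IUPAC 2021 conventional values.
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "B": 10.81, "SE": 78.971,
}

#: Mass of a proton (Da); [M+H]+ = monoisotopic + PROTON_MASS.
PROTON_MASS: float = 1.00728

#: Ideal single-bond lengths (Å) by unordered element pair, used for
#: torsion-independent extension bounds. Values are generic sp3 lengths;
#: amide C-N is handled by the sp2 flag at lookup time.
IDEAL_BOND_LENGTH: dict[frozenset, float] = {
    frozenset({"C"}): 1.53,
    frozenset({"C", "N"}): 1.46,
    frozenset({"C", "O"}): 1.42,
    frozenset({"C", "S"}): 1.81,
    frozenset({"C", "H"}): 1.09,
    frozenset({"N", "H"}): 1.01,
    frozenset({"O", "H"}): 0.96,
    frozenset({"S", "H"}): 1.34,
    frozenset({"N"}): 1.45,
    frozenset({"O"}): 1.48,
    frozenset({"S"}): 2.05,
}

#: Ideal bond angles (degrees) at a chain atom by hybridization.
IDEAL_ANGLE_SP3: float = 111.0
IDEAL_ANGLE_SP2: float = 120.0
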