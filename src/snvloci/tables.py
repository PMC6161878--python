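"""Bundled physico-chemical reference tables.

All tables are standard published constants: Kyte-Doolittle hydropathy,
Tien et al. theoretical maximum accessible surface areas, the Grantham
amino-acid distance matrix, and van-der-Waals radii used for numerical
surface-area integration.
"""

from __future__ import annotations

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenocysteine / pyrrolysine / unknown collapse to X
    "SEC": "X", "PYL": "X", "UNK": "X", "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if v != "X"}

#: Kyte-Doolittle hydropathy index (KD units), per one-letter residue code.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Theoretical maximum ASA (A^2) per residue type (Tien et al. 2013),
#: used to turn absolute ASA into relative solvent accessibility.
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: van-der-Waals radii (A) by element symbol for Shrake-Rupley ASA.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.80

# Grantham (1974) distances, upper triangle in the order the original
# table prints; symmetric, diagonal 0.
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    [174, 154, 139, 202, 154, 170, 196, 215],
    [24, 68, 32, 81, 40, 87, 115],
    [46, 53, 61, 29, 101, 130],
    [94, 23, 42, 142, 174],
    [101, 56, 95, 110],
    [45, 160, 181],
    [126, 152],
    [67],
]


def _build_grantham() -> dict[tuple[str, str], float]:
    dist: dict[tuple[str, str], float] = {}
    for aa in _GRANTHAM_ORDER:
        dist[(aa, aa)] = 0.0
    for i, row in enumerate(_GRANTHAM_UPPER):
        a = _GRANTHAM_ORDER[i]
        for j, value in enumerate(row):
            b = _GRANTHAM_ORDER[i + 1 + j]
            dist[(a, b)] = float(value)
            dist[(b, a)] = float(value)
    return dist


#: Symmetric Grantham distance lookup keyed by one-letter pairs.
GRANTHAM = _build_grantham()


def vdw_radius(element: str, default: float = DEFAULT_VDW_RADIUS) -> float:
    """Van-der-Waals radius for an element symbol, falling back to a default."""
    return VDW_RADII.get(element.strip().upper(), default)
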