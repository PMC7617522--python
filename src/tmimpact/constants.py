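"""Chemical reference tables shared across the package.

Heavy-atom van der Waals radii, amino-acid naming, charge classes and
backbone geometry live here so that every module measures distances and
builds coordinates against the same numbers.
"""

from __future__ import annotations

# Heavy-atom van der Waals radii in Angstrom.  Geometric criteria in this
# package are defined on heavy atoms only; hydrogens, when present in an
# input file, are carried through but never required.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
    "D": 1.20,
}
VDW_DEFAULT = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA: frozenset[str] = frozenset(THREE_TO_ONE)

# Common chemically modified residues mapped to the parent amino acid so
# they take part in placement and feature analysis; anything else parsed
# from HETATM records (or with an unknown name) is flagged HET and excluded.
MODIFIED_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (approximated by Cys geometry)
    "HYP": "PRO",  # hydroxyproline
    "PYL": "LYS",  # pyrrolysine
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Positively / negatively charged side chains at physiological pH.
# Histidine is ambiguous (pKa near 6) and is excluded by default; a config
# flag adds it to the positive set.
POSITIVE_AA = frozenset({"LYS", "ARG"})
NEGATIVE_AA = frozenset({"ASP", "GLU"})


def charge_sign(aa3: str, his_charged: bool = False) -> int:
    """Formal side-chain charge sign: +1, -1 or 0."""
    if aa3 in POSITIVE_AA or (his_charged and aa3 == "HIS"):
        return 1
    if aa3 in NEGATIVE_AA:
        return -1
    return 0


def normalize_aa(aa: str) -> str:
    """Accept one- or three-letter codes (any case); return the 3-letter code."""
    aa = aa.strip().upper()
    if len(aa) == 1:
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code {aa!r}")
        return ONE_TO_THREE[aa]
    if aa in STANDARD_AA:
        return aa
    if aa in MODIFIED_PARENT:
        return MODIFIED_PARENT[aa]
    raise ValueError(f"unknown amino-acid code {aa!r}")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


# Backbone covalent geometry (Engh & Huber consensus values) used by the
# synthetic builders and by mutant side-chain grafting.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5

# Salt-bridge partner atoms per charged residue type.
CARBOXYLATE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HIS_BASIC_ATOMS: tuple[str, ...] = ("ND1", "NE2")
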