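"""Side-chain construction from internal coordinates.

Each residue type carries a heavy-atom topology: every side-chain atom is
placed by the NeRF construction from three previously placed atoms with a
standard bond length, bond angle and a torsion that is either fixed (ring
and planar-group atoms) or tied to a rotatable chi angle.  The geometry is
idealised (Engh & Huber-level bond terms, default chi of 180 deg), which is
sufficient for the distance-threshold criteria this package evaluates; it
makes no claim of rotamer-library fidelity.

The same topology doubles as the covalent connectivity used to exclude
1-2 and 1-3 pairs from steric-overlap scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGLE_N_CA_CB, BOND_CA_CB
from .geometry import place_atom
from .structure import Atom, Residue

# Torsion spec: float (fixed, degrees) or ("chi", k, offset_deg).
Entry = tuple[str, str, str, str, float, float, object]

# dihedral convention: new atom X with parents (p1, p2, p3) satisfies
# dihedral(p3, p2, p1, X) == torsion and is bonded to p1.
SIDECHAIN_TOPOLOGY: dict[str, list[Entry]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "CB", "CA", "N", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "CB", "CA", "N", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "CB", "CA", "N", 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "CB", "CA", "N", 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "CB", "CA", "N", 1.527, 110.5, ("chi", 1, 120.0)),
    ],
    "LEU": [
        ("CG", "CB", "CA", "N", 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 120.0)),
    ],
    "ILE": [
        ("CG1", "CB", "CA", "N", 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0)),
        ("CD1", "CG1", "CB", "CA", 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "CG", "CB", "CA", 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "SD", "CG", "CB", 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PRO": [
        # ring approximated with fixed pucker torsions; CD closes onto N
        ("CG", "CB", "CA", "N", 1.492, 104.5, 30.0),
        ("CD", "CG", "CB", "CA", 1.503, 106.1, -35.0),
    ],
    "PHE": [
        ("CG", "CB", "CA", "N", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CD1", "CG", "CB", 1.382, 121.0, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.382, 121.0, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.372, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "CB", "CA", "N", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CD1", "CG", "CB", 1.382, 121.0, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.382, 121.0, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.372, 120.0, 0.0),
        ("OH", "CZ", "CE1", "CD1", 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "CB", "CA", "N", 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "CG", "CB", "CA", 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", "CD1", "CG", "CB", 1.374, 110.2, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.409, 107.2, 180.0),
        ("CE3", "CD2", "CG", "CB", 1.398, 133.9, 0.0),
        ("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, 180.0),
        ("CZ3", "CE3", "CD2", "CG", 1.382, 118.6, 180.0),
        ("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, 180.0),
    ],
    "ASP": [
        ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CG", "CB", "CA", 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "CG", "CB", "CA", 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CD", "CG", "CB", 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "CD", "CG", "CB", 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CG", "CB", "CA", 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "CD", "CG", "CB", 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", "CE", "CD", "CG", 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CG", "CB", "CA", 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "CD", "CG", "CB", 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", "NE", "CD", "CG", 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", "CZ", "NE", "CD", 1.326, 120.0, 0.0),
        ("NH2", "CZ", "NE", "CD", 1.326, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", "CB", "CA", "N", 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", "CG", "CB", "CA", 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", "CG", "CB", "CA", 1.354, 131.0, ("chi", 2, 180.0)),
        ("CE1", "ND1", "CG", "CB", 1.321, 109.3, 180.0),
        ("NE2", "CD2", "CG", "CB", 1.374, 107.2, 180.0),
    ],
}

# Ring-closure (and Pro CD-N) bonds not implied by the placement tree.
EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

N_CHI: dict[str, int] = {
    aa: max([t[1] for _, _, _, _, _, _, t in entries if isinstance(t, tuple)],
            default=0)
    for aa, entries in SIDECHAIN_TOPOLOGY.items()
}

# Heavy side-chain atom names (CB included) per residue type: the maximal
# allowed side-chain set for validation and stripping.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    aa: (() if aa == "GLY" else ("CB",) + tuple(e[0] for e in entries))
    for aa, entries in SIDECHAIN_TOPOLOGY.items()
}

# chi dihedral atom quadruples (N, CA, CB, G, ...) for measurement.
_CHI_CHAIN: dict[str, list[str]] = {
    aa: ["N", "CA", "CB"] + [e[0] for e in entries
                             if isinstance(e[6], tuple) and e[6][2] == 0.0]
    for aa, entries in SIDECHAIN_TOPOLOGY.items()
}


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             bond: float = BOND_CA_CB, angle: float = ANGLE_N_CA_CB) -> np.ndarray:
    """Ideal L-configuration CB from backbone N, CA, C.

    Uses the standard +122.5 deg improper torsion C-N-CA-CB, which fixes
    the L-chirality of the alpha carbon.
    """
    return place_atom(c, n, ca, bond, angle, 122.5)


def build_sidechain(aa_type: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                    chis: tuple[float, ...] = ()) -> list[tuple[str, np.ndarray]]:
    """Construct all heavy side-chain atoms for aa_type on the given backbone.

    chis supplies chi1..chiK (degrees); missing values default to 180.
    Returns [(atom_name, coord), ...] including CB (empty for GLY).
    """
    if aa_type not in SIDECHAIN_TOPOLOGY:
        raise ValueError(f"no side-chain topology for {aa_type!r}")
    if aa_type == "GLY":
        return []
    coords: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    coords["CB"] = build_cb(coords["N"], coords["CA"], coords["C"])
    out = [("CB", coords["CB"])]

    def chi(k: int) -> float:
        return chis[k - 1] if k <= len(chis) else 180.0

    for name, p1, p2, p3, bond, ang, tor in SIDECHAIN_TOPOLOGY[aa_type]:
        t = tor if isinstance(tor, float) else chi(tor[1]) + tor[2]
        pos = place_atom(coords[p3], coords[p2], coords[p1], bond, ang, float(t))
        coords[name] = pos
        out.append((name, pos))
    return out


def residue_bonds(res: Residue) -> list[tuple[str, str]]:
    """Intra-residue heavy-atom covalent bonds, from the topology tables."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    aa = res.aa_type
    if aa in SIDECHAIN_TOPOLOGY and aa != "GLY":
        bonds.append(("CA", "CB"))
        bonds += [(e[0], e[1]) for e in SIDECHAIN_TOPOLOGY[aa]]
        bonds += EXTRA_BONDS.get(aa, [])
    present = {a.name for a in res.atoms}
    return [(a, b) for a, b in bonds if a in present and b in present]


def measure_chis(res: Residue) -> list[float]:
    """Measured chi angles of a residue (degrees); empty if no chis."""
    from .geometry import dihedral
    chain = _CHI_CHAIN.get(res.aa_type, [])
    out = []
    for i in range(len(chain) - 3):
        quad = [res.atom(nm) for nm in chain[i:i + 4]]
        if any(a is None for a in quad):
            break
        out.append(dihedral(*[a.coord for a in quad]))
    return out


@dataclass(frozen=True)
class Rotamer:
    index: int
    chis: tuple[float, ...]


def load_rotamers() -> dict[str, list[Rotamer]]:
    """Rotamer sets per residue type from the packaged chi-angle table."""
    import csv
    from importlib import resources

    table: dict[str, list[Rotamer]] = {}
    with resources.files("tmimpact.data").joinpath("rotamers.csv").open() as fh:
        for row in csv.DictReader(fh):
            aa = row["residue"]
            chis = tuple(float(row[f"chi{k}"]) for k in range(1, 5)
                         if row[f"chi{k}"] != "")
            table.setdefault(aa, []).append(Rotamer(int(row["index"]), chis))
    for aa in SIDECHAIN_TOPOLOGY:
        table.setdefault(aa, [Rotamer(0, ())])
    return table
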