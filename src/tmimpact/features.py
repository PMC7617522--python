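"""Geometric feature primitives: solvent accessibility, hydrogen bonds,
salt bridges, disulphides, secondary structure and peptide omega angles.

All criteria operate on heavy atoms so that structures without hydrogens
(most experimental files and homology models) are handled identically to
protonated ones.  Contact detection uses base cutoffs from common
structural-biology practice plus a configurable slack (default +1 A) that
makes the criteria robust to the coordinate error of modelled structures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    BASIC_ATOMS, CARBOXYLATE_ATOMS, HIS_BASIC_ATOMS,
)
from .geometry import bond_angle, dihedral
from .sidechain import residue_bonds
from .structure import Residue, ResidueSelector, Structure, StructureError

AtomKey = tuple[ResidueSelector, str]


# ---------------------------------------------------------------------------
# covalent connectivity (for excluding 1-2/1-3 pairs from contact criteria)


class BondGraph:
    """Heavy-atom covalent bond graph over a whole structure: intra-residue
    bonds from the topology tables, peptide C-N links, and S-S bridges."""

    def __init__(self, s: Structure):
        self.adj: dict[AtomKey, set[AtomKey]] = {}

        def link(a: AtomKey, b: AtomKey):
            self.adj.setdefault(a, set()).add(b)
            self.adj.setdefault(b, set()).add(a)

        for ch in s.chains:
            prev: Residue | None = None
            for res in ch.residues:
                sel = res.selector
                for a, b in residue_bonds(res):
                    link((sel, a), (sel, b))
                if (prev is not None and prev.atom("C") is not None
                        and res.atom("N") is not None):
                    d = np.linalg.norm(prev.atom("C").coord - res.atom("N").coord)
                    if d < 2.0:
                        link((prev.selector, "C"), (sel, "N"))
                prev = res if res.is_amino_acid else None
        # disulphide bridges are covalent: link SG pairs at bond distance
        cys_sg = [(r.selector, r.atom("SG")) for r in s.residues(amino_only=True)
                  if r.aa_type == "CYS" and r.atom("SG") is not None]
        for i in range(len(cys_sg)):
            for j in range(i + 1, len(cys_sg)):
                d = np.linalg.norm(cys_sg[i][1].coord - cys_sg[j][1].coord)
                if d < 2.5:
                    link((cys_sg[i][0], "SG"), (cys_sg[j][0], "SG"))

    def within_bonds(self, a: AtomKey, b: AtomKey, k: int) -> bool:
        """True if a and b are separated by at most k covalent bonds."""
        frontier = {a}
        seen = {a}
        for _ in range(k):
            nxt = set()
            for x in frontier:
                nxt |= self.adj.get(x, set())
            if b in nxt:
                return True
            frontier = nxt - seen
            seen |= nxt
        return False

    def within_two_bonds(self, a: AtomKey, b: AtomKey) -> bool:
        return self.within_bonds(a, b, 2)


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley sphere sampling)


@dataclass
class SasaResult:
    atom_sasa: dict[AtomKey, float]
    residue_sasa: dict[ResidueSelector, float]
    relative: dict[ResidueSelector, float]  # RSA, standard residues only

    def rsa(self, sel: ResidueSelector) -> float | None:
        return self.relative.get(sel)


def _sphere_points(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _max_sasa_table() -> dict[str, float]:
    table = {}
    with resources.files("tmimpact.data").joinpath("max_sasa.csv").open() as fh:
        for row in csv.DictReader(r for r in fh if not r.startswith("#")):
            table[row["residue"]] = float(row["max_sasa"])
    return table


_MAX_SASA: dict[str, float] | None = None


def compute_sasa(s: Structure, probe: float = 1.4, points: int = 960
                 ) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area on heavy atoms.

    Each atom's sphere (vdW radius + probe) is sampled with `points`
    quasi-uniform points; the accessible fraction is the share of points
    not inside any neighbouring expanded sphere.  RSA is the residue total
    divided by the packaged extended Gly-X-Gly reference maximum.
    """
    global _MAX_SASA
    if _MAX_SASA is None:
        _MAX_SASA = _max_sasa_table()

    atoms: list[tuple[AtomKey, np.ndarray, float]] = []
    for res in s.residues():
        for a in res.heavy_atoms():
            atoms.append(((res.selector, a.name), a.coord,
                          a.vdw_radius + probe))
    if not atoms:
        return SasaResult({}, {}, {})
    coords = np.array([c for _, c, _ in atoms])
    radii = np.array([r for _, _, r in atoms])
    tree = cKDTree(coords)
    rmax = float(radii.max())
    sphere = _sphere_points(points)

    atom_sasa: dict[AtomKey, float] = {}
    for i, (key, ci, ri) in enumerate(atoms):
        pts = ci + ri * sphere
        nbr = [j for j in tree.query_ball_point(ci, ri + rmax) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in nbr:
            dj = np.linalg.norm(pts[accessible] - coords[j], axis=1)
            keep = dj >= radii[j]
            idx = np.where(accessible)[0]
            accessible[idx[~keep]] = False
            if not accessible.any():
                break
        frac = accessible.sum() / points
        atom_sasa[key] = float(4.0 * np.pi * ri * ri * frac)

    residue_sasa: dict[ResidueSelector, float] = {}
    for (sel, _), v in atom_sasa.items():
        residue_sasa[sel] = residue_sasa.get(sel, 0.0) + v
    relative = {}
    for res in s.residues(amino_only=True):
        ref = _MAX_SASA.get(res.aa_type)
        if ref:
            relative[res.selector] = residue_sasa.get(res.selector, 0.0) / ref
    return SasaResult(atom_sasa, residue_sasa, relative)


# ---------------------------------------------------------------------------
# contacts


@dataclass(frozen=True)
class Contact:
    kind: str            # "hbond" | "salt_bridge" | "disulphide"
    a: AtomKey
    b: AtomKey
    distance: float

    def residues(self) -> frozenset[ResidueSelector]:
        return frozenset((self.a[0], self.b[0]))

    def involves(self, sel: ResidueSelector) -> bool:
        return sel in (self.a[0], self.b[0])


def _heavy_atom_index(s: Structure, elements: frozenset[str] | None = None,
                      amino_only: bool = True):
    keys, coords = [], []
    for res in s.residues(amino_only=amino_only):
        for a in res.heavy_atoms():
            if elements is None or a.element.upper() in elements:
                keys.append((res.selector, a.name))
                coords.append(a.coord)
    return keys, (np.array(coords) if coords else np.zeros((0, 3)))


def find_hbonds(s: Structure, base_cutoff: float = 3.5, slack: float = 1.0,
                bond_graph: BondGraph | None = None) -> list[Contact]:
    """Heavy-atom hydrogen-bond candidates: N/O/S donor to N/O acceptor
    closer than base_cutoff + slack (strict), excluding intra-residue pairs
    and pairs within two covalent bonds.  When hydrogens are present on the
    donor, a donor-angle test (D-H...A > 90 degrees) is applied.
    """
    cutoff = base_cutoff + slack
    graph = bond_graph or BondGraph(s)
    dk, dc = _heavy_atom_index(s, frozenset({"N", "O", "S"}))
    ak, ac = _heavy_atom_index(s, frozenset({"N", "O"}))
    if not len(dc) or not len(ac):
        return []
    res_index = {r.selector: r for r in s.residues(amino_only=True)}
    tree = cKDTree(ac)
    seen: set[frozenset[AtomKey]] = set()
    out: list[Contact] = []
    for i, (dkey, dxyz) in enumerate(zip(dk, dc)):
        for j in tree.query_ball_point(dxyz, cutoff):
            akey = ak[j]
            if akey[0] == dkey[0]:
                continue
            pair = frozenset((dkey, akey))
            if pair in seen:
                continue
            d = float(np.linalg.norm(dxyz - ac[j]))
            if d >= cutoff or d <= 0.0:
                continue
            if graph.within_two_bonds(dkey, akey):
                continue
            if not _donor_angle_ok(res_index.get(dkey[0]), dkey[1], ac[j]):
                continue
            seen.add(pair)
            out.append(Contact("hbond", dkey, akey, d))
    out.sort(key=_contact_key)
    return out


def _donor_angle_ok(res: Residue | None, donor_name: str,
                    acceptor_xyz: np.ndarray) -> bool:
    """If the donor carries explicit hydrogens, require a plausible
    D-H...A geometry (angle at H above 90 deg for the best hydrogen)."""
    if res is None:
        return True
    donor = res.atom(donor_name)
    hydrogens = [a for a in res.atoms if a.is_hydrogen
                 and np.linalg.norm(a.coord - donor.coord) < 1.3]
    if not hydrogens:
        return True
    return any(bond_angle(donor.coord, h.coord, acceptor_xyz) > 90.0
               for h in hydrogens)


def find_salt_bridges(s: Structure, base_cutoff: float = 4.0,
                      slack: float = 1.0, his_charged: bool = False
                      ) -> list[Contact]:
    """Asp/Glu carboxylate oxygen to Lys/Arg (optionally His) basic nitrogen
    closer than base_cutoff + slack (strict).  One contact per residue pair,
    reported at the minimal qualifying atom-atom distance."""
    cutoff = base_cutoff + slack
    acid, base = [], []
    for res in s.residues(amino_only=True):
        names = CARBOXYLATE_ATOMS.get(res.aa_type)
        if names:
            acid += [((res.selector, n), res.atom(n).coord)
                     for n in names if res.atom(n) is not None]
        bnames = BASIC_ATOMS.get(res.aa_type)
        if res.aa_type == "HIS" and his_charged:
            bnames = HIS_BASIC_ATOMS
        if bnames:
            base += [((res.selector, n), res.atom(n).coord)
                     for n in bnames if res.atom(n) is not None]
    best: dict[frozenset[ResidueSelector], Contact] = {}
    for akey, axyz in acid:
        for bkey, bxyz in base:
            d = float(np.linalg.norm(axyz - bxyz))
            if d >= cutoff:
                continue
            rp = frozenset((akey[0], bkey[0]))
            if rp not in best or d < best[rp].distance:
                best[rp] = Contact("salt_bridge", akey, bkey, d)
    return sorted(best.values(), key=_contact_key)


def find_disulphides(s: Structure, base_cutoff: float = 2.3,
                     slack: float = 1.0) -> list[Contact]:
    """Cysteine SG-SG pairs closer than base_cutoff + slack (strict)."""
    cutoff = base_cutoff + slack
    sgs = [((r.selector, "SG"), r.atom("SG").coord)
           for r in s.residues(amino_only=True)
           if r.aa_type == "CYS" and r.atom("SG") is not None]
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d < cutoff:
                out.append(Contact("disulphide", sgs[i][0], sgs[j][0], d))
    return sorted(out, key=_contact_key)


def _contact_key(c: Contact):
    ka = (c.a[0].chain_id, c.a[0].seq_id, c.a[0].insertion_code, c.a[1])
    kb = (c.b[0].chain_id, c.b[0].seq_id, c.b[0].insertion_code, c.b[1])
    return tuple(sorted((ka, kb))) + (c.kind,)


# ---------------------------------------------------------------------------
# secondary structure and omega


H, E, B, C = "H", "E", "B", "C"


def assign_secondary_structure(s: Structure) -> dict[ResidueSelector, str]:
    """Simplified per-residue secondary structure: H (helix) from runs of
    i -> i+4 backbone hydrogen bonds, E (strand) from long-range backbone
    H-bond ladder partners, B (bend) from CA-trace curvature above 70
    degrees over five residues, else C.  Priority H > E > B > C."""
    labels: dict[ResidueSelector, str] = {}
    bb_bonds = _backbone_hbonds(s)
    for ch in s.chains:
        residues = [r for r in ch.residues if r.is_amino_acid]
        n = len(residues)
        lab = [C] * n
        pos = {r.selector: i for i, r in enumerate(residues)}
        # helix: O(i) ... N(i+4), stored as (donor N residue, acceptor O residue)
        for i in range(n - 4):
            if (residues[i + 4].selector, residues[i].selector) in bb_bonds:
                for k in range(i, i + 5):
                    lab[k] = H
        # strand: long-range backbone ladder partner
        for (sa, sb) in bb_bonds:
            for sel in (sa, sb):
                other = sb if sel is sa else sa
                if sel in pos:
                    i = pos[sel]
                    long_range = (other not in pos
                                  or abs(pos[other] - i) > 4)
                    if long_range and lab[i] != H:
                        lab[i] = E
        # bend: direction change of the CA trace
        for i in range(2, n - 2):
            if lab[i] != C:
                continue
            ca0 = residues[i - 2].atom("CA")
            ca1 = residues[i].atom("CA")
            ca2 = residues[i + 2].atom("CA")
            if ca0 is None or ca1 is None or ca2 is None:
                continue
            u = ca1.coord - ca0.coord
            v = ca2.coord - ca1.coord
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
                lab[i] = B
        for r, l in zip(residues, lab):
            labels[r.selector] = l
    return labels


def _backbone_hbonds(s: Structure, cutoff: float = 3.5
                     ) -> set[tuple[ResidueSelector, ResidueSelector]]:
    """(donor residue, acceptor residue) pairs with backbone N...O under
    cutoff, skipping adjacent residues (peptide 1-3 neighbours)."""
    out = set()
    res = [r for r in s.residues(amino_only=True)]
    donors = [(r.selector, r.atom("N").coord) for r in res if r.atom("N")]
    acceptors = [(r.selector, r.atom("O").coord) for r in res if r.atom("O")]
    if not donors or not acceptors:
        return out
    order = {r.selector: (r.chain_id, i) for i, r in enumerate(res)}
    tree = cKDTree(np.array([c for _, c in acceptors]))
    dcoords = np.array([c for _, c in donors])
    for i, (dsel, dxyz) in enumerate(donors):
        for j in tree.query_ball_point(dcoords[i], cutoff):
            asel = acceptors[j][0]
            if asel == dsel:
                continue
            ch_d, i_d = order[dsel]
            ch_a, i_a = order[asel]
            if ch_d == ch_a and abs(i_d - i_a) < 2:
                continue
            out.add((dsel, asel))
    return out


def helix_segments(labels: dict[ResidueSelector, str], s: Structure
                   ) -> dict[ResidueSelector, int]:
    """Map each helical residue to a helix segment id (maximal H runs,
    numbered over the whole structure)."""
    seg: dict[ResidueSelector, int] = {}
    seg_id = 0
    for ch in s.chains:
        in_run = False
        for r in ch.residues:
            if not r.is_amino_acid:
                in_run = False
                continue
            if labels.get(r.selector) == H:
                if not in_run:
                    seg_id += 1
                    in_run = True
                seg[r.selector] = seg_id
            else:
                in_run = False
    return seg


def omega_angle(s: Structure, sel: ResidueSelector) -> float:
    """Peptide omega torsion CA(i-1)-C(i-1)-N(i)-CA(i) in degrees."""
    from .structure import resolve_residue
    res = resolve_residue(s, sel)
    chain = s.chain(sel.chain_id)
    idx = chain.residues.index(res)
    if idx == 0:
        raise StructureError(f"{sel}: first residue of chain has no omega")
    prev = chain.residues[idx - 1]
    needed = [prev.atom("CA"), prev.atom("C"), res.atom("N"), res.atom("CA")]
    if any(a is None for a in needed):
        raise StructureError(f"{sel}: incomplete backbone for omega")
    return dihedral(*[a.coord for a in needed])


def is_cis(omega: float, threshold: float = 30.0) -> bool:
    return abs(omega) < threshold


# ---------------------------------------------------------------------------
# aggregate context used by the classifiers


@dataclass
class FeatureContext:
    """All computed features of one structure, shared by the evaluators."""
    structure: Structure
    sasa: SasaResult
    hbonds: list[Contact]
    salt_bridges: list[Contact]
    disulphides: list[Contact]
    ss: dict[ResidueSelector, str]
    helix_of: dict[ResidueSelector, int] = field(default_factory=dict)


def compute_features(s: Structure, cfg=None) -> FeatureContext:
    from .config import RunConfig
    cfg = cfg or RunConfig()
    graph = BondGraph(s)
    ss = assign_secondary_structure(s)
    return FeatureContext(
        structure=s,
        sasa=compute_sasa(s, probe=cfg.sasa_probe, points=cfg.sasa_points),
        hbonds=find_hbonds(s, cfg.hbond_base, cfg.slack, graph),
        salt_bridges=find_salt_bridges(s, cfg.salt_bridge_base, cfg.slack,
                                       cfg.his_charged),
        disulphides=find_disulphides(s, cfg.disulphide_base, cfg.slack),
        ss=ss,
        helix_of=helix_segments(ss, s),
    )
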