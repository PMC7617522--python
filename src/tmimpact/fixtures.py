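"""Deterministic synthetic structures with known ground truth.

Every builder constructs coordinates from ideal internal geometry (NeRF),
so each fixture carries exact, generator-derived truth: helix tilt, region
labels inside the default 30 A slab, contact distances placed to within
1e-6 A, and backbone omega angles.  Tests for the placement search, the
contact detectors and the damage classifiers assert against this metadata
rather than against any external reference.

The generators emulate idealised single-pass and multi-pass helical
membrane proteins; they do not attempt lipids, curved bilayers or
thermal disorder beyond optional Gaussian jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_N_CA_C,
    BOND_C_N, BOND_C_O, BOND_CA_C, BOND_N_CA,
    ONE_TO_THREE, normalize_aa,
)
from .geometry import (
    helix_axis, place_atom, rotation_about_axis, rotation_aligning,
    rotation_x, rotation_z, unit,
)
from .sidechain import build_sidechain
from .structure import Atom, Chain, Residue, Structure

FIXTURE_KINDS = ("ideal_helix", "helix_bundle", "contact_motif",
                 "cis_peptide", "extended_chain")


@dataclass
class FixtureSpec:
    kind: str = "ideal_helix"
    length: int = 20
    sequence: str = ""
    tilt_deg: float = 0.0
    contact_distance: float = 3.0
    motif: str = "salt_bridge"      # salt_bridge | disulphide | hbond
    n_helices: int = 1
    seed: int = 0
    jitter: float = 0.0             # A; optional coordinate noise

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not self.sequence:
            self.sequence = default_tm_sequence(self.length)
        if len(self.sequence) != self.length:
            raise ValueError("sequence length must equal length")
        if self.contact_distance <= 0:
            raise ValueError("contact_distance must be > 0")


def default_tm_sequence(length: int) -> str:
    """Hydrophobic leucine core with lysine anchors at both termini.

    The charged flanks emulate the positively charged residues that border
    natural transmembrane segments; they are what makes the minimum of the
    transfer energy a membrane-spanning orientation rather than a surface-
    parallel one.
    """
    if length <= 4:
        return "L" * length
    return "KK" + "L" * (length - 4) + "KK"


# ---------------------------------------------------------------------------
# backbone construction


def build_chain(sequence: str, phi, psi, omega=180.0, chain_id: str = "A",
                start_seq: int = 1, chis: tuple[float, ...] = ()) -> Structure:
    """Poly-peptide from per-residue (phi, psi, omega) internal coordinates.

    phi/psi/omega may be scalars or sequences of len(sequence) values;
    omega[i] is the peptide torsion preceding residue i (omega[0] unused).
    Side chains are built at the default rotamer.
    """
    n = len(sequence)
    aa3 = [normalize_aa(c) for c in sequence]
    phi = _per_residue(phi, n)
    psi = _per_residue(psi, n)
    omega = _per_residue(omega, n)

    # first residue backbone in the xy-plane
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            BOND_C_N, ANGLE_CA_C_N, psi[i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             BOND_N_CA, ANGLE_C_N_CA, omega[i]))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            BOND_CA_C, ANGLE_N_CA_C, phi[i]))
    O = []
    for i in range(n):
        if i + 1 < n:
            O.append(place_atom(N[i + 1], CA[i], C[i],
                                BOND_C_O, ANGLE_CA_C_O, 180.0))
        else:
            O.append(place_atom(N[i], CA[i], C[i],
                                BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0))

    ch = Chain(chain_id=chain_id)
    for i, aa in enumerate(aa3):
        res = Residue(chain_id=chain_id, seq_id=start_seq + i, aa_type=aa)
        for nm, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            res.atoms.append(Atom(name=nm, element=nm[0], coord=pos))
        for nm, pos in build_sidechain(aa, N[i], CA[i], C[i], chis):
            res.atoms.append(Atom(name=nm, element=nm[0], coord=pos))
        ch.residues.append(res)
    return Structure(chains=[ch], id=f"synth-{chain_id}", source_format="pdb")


def _per_residue(v, n: int) -> list[float]:
    if np.isscalar(v):
        return [float(v)] * n
    v = list(v)
    if len(v) != n:
        raise ValueError("per-residue angle list has wrong length")
    return [float(x) for x in v]


def _all_coords(s: Structure) -> np.ndarray:
    return np.array([a.coord for r in s.residues() for a in r.atoms])


def _apply(s: Structure, rot: np.ndarray | None = None,
           shift: np.ndarray | None = None) -> None:
    for r in s.residues():
        for a in r.atoms:
            if rot is not None:
                a.coord = rot @ a.coord
            if shift is not None:
                a.coord = a.coord + shift


def _ca_coords(s: Structure) -> np.ndarray:
    return np.array([r.atom("CA").coord for r in s.residues(amino_only=True)])


def _jitter(s: Structure, spec: FixtureSpec) -> None:
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for r in s.residues():
            for a in r.atoms:
                a.coord = a.coord + rng.normal(0.0, spec.jitter, 3)


# ---------------------------------------------------------------------------
# fixture builders


def build_ideal_helix(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Canonical alpha-helix (phi=-57, psi=-47, omega=180), axis tilted
    tilt_deg from Z, CA centroid at the origin."""
    s = build_chain(spec.sequence, phi=-57.0, psi=-47.0, omega=180.0)
    ca = _ca_coords(s)
    if len(ca) >= 4:
        rot = rotation_aligning(helix_axis(ca), np.array([0.0, 0.0, 1.0]))
        _apply(s, rot=rot)
    _apply(s, shift=-_ca_coords(s).mean(axis=0))
    if spec.tilt_deg:
        _apply(s, rot=rotation_x(spec.tilt_deg))
    _jitter(s, spec)
    truth = {
        "kind": "ideal_helix",
        "tilt_deg": spec.tilt_deg,
        "sequence": spec.sequence,
        "regions": _depth_truth(s),
        "axis": _axis_truth(s),
    }
    return s, truth


def build_extended_chain(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Fully extended backbone (phi = psi = 180): no helical H-bond ladder."""
    s = build_chain(spec.sequence, phi=180.0, psi=180.0)
    _jitter(s, spec)
    return s, {"kind": "extended_chain", "sequence": spec.sequence}


def build_cis_peptide(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Short peptide with a cis (omega = 0) bond before its middle residue."""
    n = max(spec.length, 3)
    seq = spec.sequence if len(spec.sequence) == n else "A" + "P" + "A" * (n - 2)
    mid = n // 2
    omegas = [180.0] * n
    omegas[mid] = 0.0
    s = build_chain(seq, phi=-75.0, psi=150.0, omega=omegas)
    _jitter(s, spec)
    return s, {"kind": "cis_peptide", "cis_position": mid + 1,
               "sequence": seq}


# defining atom pair per contact motif: (residue A, atom A, residue B, atom B)
MOTIF_ATOMS = {
    "salt_bridge": ("E", "OE1", "K", "NZ"),
    "disulphide": ("C", "SG", "C", "SG"),
    "hbond": ("S", "OG", "N", "ND2"),
}


def build_contact_motif(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Two single-residue chains posed so the motif-defining atom pair sits
    at exactly contact_distance along +x, with both residues pointing away
    from the contact so the defining pair is the closest relevant pair."""
    if spec.motif not in MOTIF_ATOMS:
        raise ValueError(f"unknown motif {spec.motif!r}")
    aa1, at1, aa2, at2 = MOTIF_ATOMS[spec.motif]
    s1 = build_chain(aa1, phi=-57.0, psi=-47.0, chain_id="A")
    s2 = build_chain(aa2, phi=-57.0, psi=-47.0, chain_id="B", chis=(180.0, 180.0, 180.0, 180.0))
    r1 = s1.chains[0].residues[0]
    r2 = s2.chains[0].residues[0]
    # orient so the defining atom of each residue is its +x / -x extreme
    _orient_extremal(s1, r1.atom(at1).coord, np.array([1.0, 0.0, 0.0]))
    _orient_extremal(s2, r2.atom(at2).coord, np.array([-1.0, 0.0, 0.0]))
    shift = (r1.atom(at1).coord + np.array([spec.contact_distance, 0, 0])
             - r2.atom(at2).coord)
    _apply(s2, shift=shift)
    s = Structure(chains=[s1.chains[0], s2.chains[0]], id="motif",
                  source_format="pdb")
    _jitter(s, spec)
    d = float(np.linalg.norm(r1.atom(at1).coord - r2.atom(at2).coord))
    truth = {"kind": "contact_motif", "motif": spec.motif,
             "pair": [f"A/1:{at1}", f"B/1:{at2}"], "distance": d}
    return s, truth


def _orient_extremal(s: Structure, anchor: np.ndarray, direction: np.ndarray,
                     tol: float = 1e-9) -> None:
    """Rotate s about the origin of its centroid so that `anchor` becomes the
    structure's extreme point along `direction`."""
    coords = _all_coords(s)
    cen = coords.mean(axis=0)
    _apply(s, shift=-cen)
    rot = rotation_aligning(anchor - cen, direction)
    _apply(s, rot=rot)


def build_tm_bundle(n_helices: int, spec: FixtureSpec) -> tuple[Structure, dict]:
    """Bundle of ideal vertical helices on a circle (radius 8 A), alternate
    helices antiparallel, all spanning the default slab; a single chain with
    a numbering gap of 100 between consecutive helices."""
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    radius = 0.0 if n_helices == 1 else 8.0
    ch = Chain(chain_id="A")
    for h in range(n_helices):
        sub = build_chain(spec.sequence, phi=-57.0, psi=-47.0,
                          chain_id="A", start_seq=100 * h + 1)
        ca = _ca_coords(sub)
        if len(ca) >= 4:
            rot = rotation_aligning(helix_axis(ca), np.array([0.0, 0.0, 1.0]))
            _apply(sub, rot=rot)
        _apply(sub, shift=-_ca_coords(sub).mean(axis=0))
        if h % 2 == 1:
            _apply(sub, rot=rotation_x(180.0))
        theta = 360.0 * h / n_helices
        pos = rotation_z(theta) @ np.array([radius, 0.0, 0.0])
        _apply(sub, shift=pos)
        ch.residues.extend(sub.chains[0].residues)
    s = Structure(chains=[ch], id=f"bundle-{n_helices}", source_format="pdb")
    _jitter(s, spec)
    truth = {"kind": "helix_bundle", "n_helices": n_helices,
             "sequence": spec.sequence, "regions": _depth_truth(s)}
    return s, truth


def _depth_truth(s: Structure) -> dict[str, str]:
    """Ground-truth region labels straight from generator z coordinates."""
    from .placement import region_from_depth
    out = {}
    for res in s.residues(amino_only=True):
        a = res.atom("CA")
        if a is not None:
            out[str(res.selector)] = region_from_depth(abs(float(a.coord[2])))
    return out


def _axis_truth(s: Structure) -> list[float]:
    ca = _ca_coords(s)
    if len(ca) < 4:
        return [0.0, 0.0, 1.0]
    return [float(x) for x in helix_axis(ca)]


# ---------------------------------------------------------------------------
# composite fixtures used by the classifier tests


def build_hbond_helix_pair(donor_aa: str = "S", target_distance: float = 2.9
                           ) -> tuple[Structure, dict]:
    """Two parallel leucine helices (chains A and B) joined by one
    side-chain hydrogen bond: donor (Ser/Thr) on A mid-helix to the Asn
    carbonyl oxygen OD1 on B, posed at target_distance."""
    donor_aa = donor_aa.upper()
    one = donor_aa if len(donor_aa) == 1 else {"SER": "S", "THR": "T"}[donor_aa]
    seq_a = "LLLLL" + one + "LLLLL"
    seq_b = "LLLLLNLLLLL"
    sa = _vertical_helix(seq_a, "A")
    sb = _vertical_helix(seq_b, "B")
    res_a = sa.chains[0].residues[5]
    res_b = sb.chains[0].residues[5]
    donor_atom = "OG" if one == "S" else "OG1"
    # face the two side chains towards each other across the x-axis
    _face_x(sa, res_a.atom("CB").coord, +1.0)
    _face_x(sb, res_b.atom("CB").coord, -1.0)
    d_atom = res_a.atom(donor_atom).coord
    a_atom = res_b.atom("OD1").coord
    shift_x = target_distance - (a_atom[0] - d_atom[0])
    _apply(sb, shift=np.array([shift_x, d_atom[1] - a_atom[1],
                               d_atom[2] - a_atom[2]]))
    s = Structure(chains=[sa.chains[0], sb.chains[0]], id="helix-pair",
                  source_format="pdb")
    truth = {"donor": f"A/6:{donor_atom}", "acceptor": "B/6:OD1",
             "distance": float(np.linalg.norm(
                 res_a.atom(donor_atom).coord - res_b.atom("OD1").coord))}
    return s, truth


def _vertical_helix(sequence: str, chain_id: str) -> Structure:
    s = build_chain(sequence, phi=-57.0, psi=-47.0, chain_id=chain_id)
    ca = _ca_coords(s)
    rot = rotation_aligning(helix_axis(ca), np.array([0.0, 0.0, 1.0]))
    _apply(s, rot=rot)
    _apply(s, shift=-_ca_coords(s).mean(axis=0))
    return s


def _face_x(s: Structure, anchor: np.ndarray, sign: float) -> None:
    """Rotate a vertical helix about Z so `anchor` faces along sign*x."""
    ang = np.degrees(np.arctan2(anchor[1], anchor[0]))
    target = 0.0 if sign > 0 else 180.0
    _apply(s, rot=rotation_z(target - ang))


def build_buried_gly_bend(shell_radius: float = 6.0, n_shell: int = 42
                          ) -> tuple[Structure, dict]:
    """A hairpin peptide with glycine at the turn, buried inside a shell of
    alanine residues.

    The backbone runs extended, turns sharply at the central glycine
    (CA-trace curvature above the 70 degree bend criterion) and runs back;
    the surrounding alanine shell (chain S) occludes the glycine so its
    relative accessibility falls below the buried threshold.
    """
    n = 9
    seq = "AAAAGAAAA"
    phis = [-120.0] * n
    psis = [120.0] * n
    phis[4], psis[4] = 80.0, -60.0
    phis[3], psis[3] = -60.0, -30.0
    s = build_chain(seq, phi=phis, psi=psis, chain_id="A")
    gly = s.chains[0].residues[4]
    _apply(s, shift=-gly.atom("CA").coord)

    shell = Chain(chain_id="S")
    pts = _fibonacci_sphere(n_shell)
    num = 1
    for layer, r in ((0, shell_radius), (1, shell_radius + 2.6)):
        for p in pts:
            if layer == 1:
                p = rotation_z(22.5) @ p
            centre = r * p
            if _near_backbone(s, centre, 3.2):
                continue
            res = _ala_at(centre, "S", num)
            shell.residues.append(res)
            num += 1
    out = Structure(chains=[s.chains[0], shell], id="buried-bend",
                    source_format="pdb")
    return out, {"target": "A/5", "shell_residues": len(shell.residues)}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _near_backbone(s: Structure, point: np.ndarray, cutoff: float) -> bool:
    for res in s.residues():
        for a in res.atoms:
            if np.linalg.norm(a.coord - point) < cutoff:
                return True
    return False


def _ala_at(centre: np.ndarray, chain_id: str, seq_id: int) -> Residue:
    """Compact occluder residue at `centre` for the burial shell.

    Flagged HET so the shell blocks solvent in the SASA computation but
    stays out of secondary-structure assignment, placement energetics and
    repacking."""
    tmpl = build_chain("A", phi=-57.0, psi=-47.0)
    res = tmpl.chains[0].residues[0]
    shift = centre - res.atom("CA").coord
    out = Residue(chain_id=chain_id, seq_id=seq_id, aa_type="HET", het=True,
                  name="SHL")
    for a in res.atoms:
        out.atoms.append(Atom(name=a.name, element=a.element,
                              coord=a.coord + shift))
    return out


def build_gxg(aa_one: str) -> Structure:
    """Extended Gly-X-Gly tripeptide (reference state for relative SASA)."""
    seq = "G" + aa_one.upper() + "G"
    return build_chain(seq, phi=-120.0, psi=140.0)


# ---------------------------------------------------------------------------
# dispatch + sidecar output


def build_fixture(spec: FixtureSpec) -> tuple[Structure, dict]:
    if spec.kind == "ideal_helix":
        return build_ideal_helix(spec)
    if spec.kind == "helix_bundle":
        return build_tm_bundle(spec.n_helices, spec)
    if spec.kind == "contact_motif":
        return build_contact_motif(spec)
    if spec.kind == "cis_peptide":
        return build_cis_peptide(spec)
    if spec.kind == "extended_chain":
        return build_extended_chain(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def write_fixture(spec: FixtureSpec, outdir: str, basename: str) -> dict:
    """Write PDB + mmCIF + JSON ground-truth sidecar; returns file paths."""
    import os

    from .structure import write_structure
    s, truth = build_fixture(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pdb": os.path.join(outdir, basename + ".pdb"),
        "cif": os.path.join(outdir, basename + ".cif"),
        "json": os.path.join(outdir, basename + ".json"),
    }
    write_structure(s, paths["pdb"])
    write_structure(s, paths["cif"])
    with open(paths["json"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
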