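"""Mutant structure construction: neighbourhood stripping, side-chain
grafting and deterministic rotamer repacking.

The protocol mirrors common variant-modelling practice: the target side
chain and the side chains of every residue with any heavy atom closer than
5 A to the target are removed, the variant side chain is grafted onto the
fixed backbone, and the stripped side chains are rebuilt.  The default
repacker enumerates a packaged chi-angle rotamer set per residue type and
greedily picks the least-clashing rotamer, nearest residue first, with a
fixed tie-break - it is fully deterministic and makes no claim of
energy-function fidelity.  An adapter for an external SCWRL4 executable is
available behind a configuration flag with the same input/output contract.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import BACKBONE_ATOMS, THREE_TO_ONE, normalize_aa
from .features import BondGraph
from .sidechain import SIDECHAIN_ATOMS, build_sidechain, load_rotamers
from .structure import (
    Residue, ResidueSelector, Structure, StructureError, resolve_residue,
)


class VariantError(StructureError):
    pass


class WildTypeMismatchError(VariantError):
    pass


@dataclass
class RepackJob:
    target: ResidueSelector
    wt_aa: str
    mut_aa: str
    neighbourhood: list[ResidueSelector] = field(default_factory=list)
    repacker: str = "internal_rotamer"

    def __post_init__(self):
        self.wt_aa = normalize_aa(self.wt_aa)
        self.mut_aa = normalize_aa(self.mut_aa)
        self.neighbourhood = [sel for sel in self.neighbourhood
                              if sel != self.target]


@dataclass
class VariantModel:
    wild_type: Structure
    mutant: Structure
    job: RepackJob
    clash_score: float


def find_neighbourhood(s: Structure, target: ResidueSelector,
                       radius: float = 5.0) -> list[ResidueSelector]:
    """Residues with any heavy atom strictly closer than `radius` to any
    heavy atom of the target residue (the target itself excluded)."""
    tres = resolve_residue(s, target)
    tcoords = tres.heavy_coords()
    if not len(tcoords):
        return []
    tree = cKDTree(tcoords)
    out = []
    for res in s.residues(amino_only=True):
        if res.selector == target:
            continue
        coords = res.heavy_coords()
        if not len(coords):
            continue
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) < radius:
            out.append(res.selector)
    return out


def clash_score(s: Structure, scope: list[ResidueSelector] | None = None,
                bond_graph: BondGraph | None = None) -> float:
    """Worst heavy-atom van der Waals overlap in Angstrom (floored at 0).

    Overlap of a pair is (r_i + r_j - d); covalently near pairs (up to
    three bonds apart, i.e. 1-2/1-3/1-4) are excluded so that ideal
    isolated residues score zero.  With `scope`, only pairs involving at
    least one atom of the scoped residues are considered.
    """
    graph = bond_graph or BondGraph(s)
    keys, coords, radii = [], [], []
    for res in s.residues():
        for a in res.heavy_atoms():
            keys.append((res.selector, a.name))
            coords.append(a.coord)
            radii.append(a.vdw_radius)
    if len(coords) < 2:
        return 0.0
    coords = np.array(coords)
    radii = np.array(radii)
    in_scope = None
    if scope is not None:
        ss = set(scope)
        in_scope = np.array([k[0] in ss for k in keys])
        if not in_scope.any():
            return 0.0
    tree = cKDTree(coords)
    worst = 0.0
    maxsum = 2.0 * float(radii.max())
    for i, j in tree.query_pairs(maxsum):
        if in_scope is not None and not (in_scope[i] or in_scope[j]):
            continue
        overlap = radii[i] + radii[j] - float(np.linalg.norm(coords[i] - coords[j]))
        if overlap <= worst:
            continue
        if graph.within_bonds(keys[i], keys[j], 3):
            continue
        worst = overlap
    return worst


def _strip_sidechain(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]


def _graft(res: Residue, aa_type: str, chis: tuple[float, ...]) -> None:
    """Replace the residue's side chain with aa_type at the given rotamer."""
    from .structure import Atom
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise VariantError(f"{res.label()}: incomplete backbone (N/CA/C needed)")
    _strip_sidechain(res)
    res.aa_type = aa_type
    res.name = aa_type
    for nm, pos in build_sidechain(aa_type, n.coord, ca.coord, c.coord, chis):
        res.atoms.append(Atom(name=nm, element=nm[0], coord=pos))


class _Context:
    """Mutable atom soup the greedy repacker scores candidates against."""

    def __init__(self, s: Structure, exclude: set[ResidueSelector]):
        self.keys: list[tuple[ResidueSelector, str]] = []
        self.coords: list[np.ndarray] = []
        self.radii: list[float] = []
        for res in s.residues():
            sel = res.selector
            for a in res.heavy_atoms():
                if sel in exclude and a.name not in BACKBONE_ATOMS:
                    continue
                self.add((sel, a.name), a.coord, a.vdw_radius)

    def add(self, key, coord, radius):
        self.keys.append(key)
        self.coords.append(np.asarray(coord, float))
        self.radii.append(float(radius))

    def arrays(self):
        return np.array(self.coords), np.array(self.radii)


def _repack_internal(s: Structure, job: RepackJob, radius_order: list,
                     graph_builder) -> Structure:
    """Greedy nearest-first rotamer placement for target + neighbourhood."""
    from .constants import vdw_radius
    rotamers = load_rotamers()
    mutant = s.copy()
    to_pack = [(job.target, job.mut_aa)] + [
        (sel, resolve_residue(mutant, sel).aa_type) for sel in radius_order]
    ctx = _Context(mutant, exclude={sel for sel, _ in to_pack})
    graph = graph_builder(mutant)

    for sel, aa in to_pack:
        res = resolve_residue(mutant, sel)
        n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
        if n is None or ca is None or c is None:
            raise VariantError(f"{res.label()}: incomplete backbone")
        # graft at the default rotamer first so the bond graph knows the
        # new side chain's connectivity while candidates are scored
        _graft(res, aa, ())
        graph = graph_builder(mutant)
        best = None
        for rot in rotamers[aa]:
            atoms = build_sidechain(aa, n.coord, ca.coord, c.coord, rot.chis)
            if not atoms:
                best = (0.0, rot.index, atoms)
                break
            cand_coords = np.array([p for _, p in atoms])
            cand_radii = np.array([vdw_radius(nm[0]) for nm, _ in atoms])
            ctx_coords, ctx_radii = ctx.arrays()
            d = np.linalg.norm(cand_coords[:, None, :] - ctx_coords[None, :, :],
                               axis=-1)
            overlap = cand_radii[:, None] + ctx_radii[None, :] - d
            # zero out covalently-near pairs (side chain vs own backbone etc.)
            for ia, (nm, _) in enumerate(atoms):
                for ib, key in enumerate(ctx.keys):
                    if overlap[ia, ib] > 0.0 and graph.within_bonds(
                            (sel, nm), key, 3):
                        overlap[ia, ib] = 0.0
            score = float(np.clip(overlap, 0.0, None).sum())
            key = (round(score, 9), rot.index)
            if best is None or key < (round(best[0], 9), best[1]):
                best = (score, rot.index, atoms)
        # overwrite the grafted side chain with the chosen rotamer
        chosen = {nm: pos for nm, pos in best[2]}
        for a in res.atoms:
            if a.name in chosen:
                a.coord = chosen[a.name]
        for a in res.atoms:
            if a.name not in BACKBONE_ATOMS:
                ctx.add((sel, a.name), a.coord, a.vdw_radius)
    return mutant


def mutate_and_repack(s: Structure, job: RepackJob,
                      neighbourhood_radius: float = 5.0,
                      scwrl4_path: str = "") -> VariantModel:
    """Build the variant structure for a RepackJob.

    Raises WildTypeMismatchError when the residue found in the structure is
    not job.wt_aa, and VariantError for a same-residue substitution.
    """
    tres = resolve_residue(s, job.target)
    if not tres.is_amino_acid:
        raise VariantError(f"{tres.label()}: target is not a standard residue")
    if tres.aa_type != job.wt_aa:
        raise WildTypeMismatchError(
            f"wild-type mismatch at {job.target}: structure has "
            f"{tres.aa_type}, job says {job.wt_aa}")
    if job.mut_aa == job.wt_aa:
        raise VariantError("mutant equals wild type; nothing to model")
    if not job.neighbourhood:
        job.neighbourhood = find_neighbourhood(s, job.target,
                                               neighbourhood_radius)

    # nearest-first deterministic packing order
    tcoords = tres.heavy_coords()
    tree = cKDTree(tcoords)

    def dist(sel: ResidueSelector) -> float:
        coords = resolve_residue(s, sel).heavy_coords()
        d, _ = tree.query(coords, k=1)
        return float(np.min(d))

    order = sorted(job.neighbourhood,
                   key=lambda sel: (dist(sel), sel.chain_id, sel.seq_id,
                                    sel.insertion_code))

    if job.repacker == "external_scwrl4":
        mutant = _repack_scwrl4(s, job, scwrl4_path)
    else:
        mutant = _repack_internal(s, job, order, BondGraph)

    model = VariantModel(
        wild_type=s, mutant=mutant, job=job,
        clash_score=clash_score(mutant, [job.target] + order))
    _check_invariants(model)
    return model


def _check_invariants(m: VariantModel) -> None:
    """Backbone identity, mutant residue type, and locality."""
    touched = {m.job.target, *m.job.neighbourhood}
    wt_res = {r.selector: r for r in m.wild_type.residues()}
    for res in m.mutant.residues():
        w = wt_res.get(res.selector)
        if w is None:
            continue
        for name in BACKBONE_ATOMS:
            a, b = res.atom(name), w.atom(name)
            if (a is None) != (b is None):
                raise VariantError(f"{res.label()}: backbone atoms changed")
            if a is not None and np.max(np.abs(a.coord - b.coord)) > 1e-6:
                raise VariantError(f"{res.label()}: backbone moved")
        if res.selector not in touched and res.is_amino_acid:
            if {x.name for x in res.atoms} != {x.name for x in w.atoms}:
                raise VariantError(f"{res.label()}: untouched residue modified")
    tgt = resolve_residue(m.mutant, m.job.target)
    if tgt.aa_type != m.job.mut_aa:
        raise VariantError("mutant residue type mismatch after repack")
    allowed = set(BACKBONE_ATOMS) | set(SIDECHAIN_ATOMS.get(tgt.aa_type, ()))
    extra = {a.name for a in tgt.heavy_atoms()} - allowed
    if extra:
        raise VariantError(f"unexpected atoms on mutant residue: {extra}")


# ---------------------------------------------------------------------------
# external SCWRL4 adapter


def _repack_scwrl4(s: Structure, job: RepackJob, exe: str) -> Structure:
    """Shell out to an SCWRL4 executable; enforces the same invariants."""
    import os

    from .structure import read_structure, write_structure
    exe = exe or shutil.which("Scwrl4") or shutil.which("scwrl4") or ""
    if not exe or not os.path.exists(exe):
        raise VariantError(
            "external_scwrl4 repacker selected but no SCWRL4 executable "
            "configured; set scwrl4_path or use internal_rotamer")
    stripped = s.copy()
    tres = resolve_residue(stripped, job.target)
    _graft(tres, job.mut_aa, ())
    for sel in job.neighbourhood:
        _strip_sidechain(resolve_residue(stripped, sel))
    with tempfile.TemporaryDirectory() as tmp:
        pin = os.path.join(tmp, "in.pdb")
        pout = os.path.join(tmp, "out.pdb")
        write_structure(stripped, pin)
        seqfile = os.path.join(tmp, "seq.txt")
        with open(seqfile, "w") as fh:
            fh.write(_scwrl_sequence(stripped, job))
        proc = subprocess.run([exe, "-i", pin, "-o", pout, "-s", seqfile],
                              capture_output=True, text=True)
        if proc.returncode != 0 or not os.path.exists(pout):
            raise VariantError(f"SCWRL4 failed: {proc.stderr[:500]}")
        return read_structure(pout, format_hint="pdb")


def _scwrl_sequence(s: Structure, job: RepackJob) -> str:
    """SCWRL sequence file: lower case = fixed, upper case = repack."""
    mobile = {job.target, *job.neighbourhood}
    out = []
    for res in s.residues(amino_only=True):
        one = THREE_TO_ONE[res.aa_type]
        out.append(one.upper() if res.selector in mobile else one.lower())
    return "".join(out) + "\n"
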