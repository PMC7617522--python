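"""Macromolecular structure data model and PDB/mmCIF input-output.

A deliberately small in-memory hierarchy (Structure > Chain > Residue >
Atom) carrying exactly what the downstream geometry needs: author
numbering, element-derived van der Waals radii, and a HET flag.  Parsing
and serialisation are delegated to gemmi; alternate locations are resolved
to the highest-occupancy conformer (ties broken by file order).
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace

import numpy as np

try:
    import gemmi
except ImportError as _e:  # pragma: no cover
    gemmi = None
    _gemmi_error = _e

from .constants import (
    BACKBONE_ATOMS,
    MODIFIED_PARENT,
    STANDARD_AA,
    vdw_radius,
)


class StructureError(Exception):
    """Base class for structure-model failures."""


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class ResidueNotFoundError(StructureError):
    pass


class AmbiguousSelectorError(StructureError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # 3-vector, Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: bad coordinates {self.coord}")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radius(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    insertion_code: str = ""
    aa_type: str = "HET"   # 3-letter standard code, or "HET"
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False
    name: str = ""         # name as written in the file (e.g. MSE)

    def __post_init__(self):
        if not self.name:
            self.name = self.aa_type

    @property
    def is_amino_acid(self) -> bool:
        return not self.het and self.aa_type in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone_complete(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()], dtype=float)

    @property
    def selector(self) -> "ResidueSelector":
        return ResidueSelector(self.chain_id, self.seq_id, self.insertion_code)

    def label(self) -> str:
        ic = self.insertion_code or ""
        return f"{self.chain_id}/{self.aa_type}{self.seq_id}{ic}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass(frozen=True)
class ResidueSelector:
    chain_id: str
    seq_id: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.seq_id}{self.insertion_code}"


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    id: str = ""
    source_format: str = "pdb"  # "pdb" | "mmcif"

    def residues(self, amino_only: bool = False):
        for ch in self.chains:
            for res in ch.residues:
                if amino_only and not res.is_amino_acid:
                    continue
                yield res

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def validate(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids: {ids}")
        if not any(r.is_amino_acid for r in self.residues()):
            raise EmptyStructureError("structure contains no amino-acid residues")


def resolve_residue(s: Structure, sel: ResidueSelector) -> Residue:
    """Return the unique residue matching the selector, or raise."""
    chain = s.chain(sel.chain_id)
    if chain is None:
        raise ResidueNotFoundError(
            f"chain {sel.chain_id!r} not found (available: "
            f"{[c.chain_id for c in s.chains]})")
    icode = sel.insertion_code or ""
    hits = [r for r in chain.residues
            if r.seq_id == sel.seq_id and (r.insertion_code or "") == icode]
    if not hits:
        nums = sorted(r.seq_id for r in chain.residues)
        near = [n for n in nums if abs(n - sel.seq_id) <= 5] or nums[:5]
        raise ResidueNotFoundError(
            f"residue {sel} not found; nearby numbering in chain "
            f"{sel.chain_id}: {near}")
    if len(hits) > 1:
        raise AmbiguousSelectorError(f"selector {sel} matches {len(hits)} residues")
    return hits[0]


# ---------------------------------------------------------------------------
# gemmi-backed reading and writing


def _classify(resname: str, het_record: bool) -> tuple[str, bool]:
    """Map a residue name to (aa_type, het flag)."""
    if resname in STANDARD_AA:
        return resname, False
    if resname in MODIFIED_PARENT:
        return MODIFIED_PARENT[resname], False
    return "HET", True


def _pick_altlocs(atoms) -> list:
    """Resolve alternate locations to highest occupancy, first-in-file tie."""
    best: dict[str, object] = {}
    order: list[str] = []
    for at in atoms:
        if at.name not in best:
            best[at.name] = at
            order.append(at.name)
        elif at.occ > best[at.name].occ + 1e-9:
            best[at.name] = at
    return [best[n] for n in order]


def read_structure(path: str | os.PathLike, format_hint: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into the package's Structure model.

    Hydrogens are retained when present; HETATM residues are flagged and
    excluded from all downstream energetics/feature analysis unless they map
    to a standard parent (e.g. MSE -> MET).
    """
    if gemmi is None:  # pragma: no cover
        raise ImportError(f"gemmi is required for structure I/O: {_gemmi_error}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"file not found: {path}")
    fmt = (format_hint or "").lower()
    try:
        if fmt in ("pdb",):
            st = gemmi.read_pdb(path)
            source = "pdb"
        elif fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
            source = "mmcif"
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
            source = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"cannot parse {path}: {e}") from e

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    out = Structure(id=st.name or os.path.basename(path), source_format=source)
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            aa_type, het = _classify(res.name, res.het_flag == "H")
            r = Residue(
                chain_id=ch.name,
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa_type=aa_type,
                het=het,
                name=res.name,
            )
            for at in _pick_altlocs(res):
                r.atoms.append(Atom(
                    name=at.name,
                    element=at.element.name.upper(),
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=(at.altloc or "").strip(),
                ))
            if r.atoms:
                chain.residues.append(r)
        if chain.residues:
            out.chains.append(chain)
    out.validate()
    return out


def _to_gemmi(s: Structure) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = s.id or "XXXX"
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if res.het else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                ga.altloc = "\0"
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | os.PathLike) -> None:
    """Write PDB (default) or mmCIF, chosen by file extension (.cif/.mmcif)."""
    path = os.fspath(path)
    st = _to_gemmi(s)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".cif", ".mmcif"):
            st.make_mmcif_document().write_file(path)
        else:
            st.write_pdb(path)
    except (OSError, RuntimeError) as e:
        raise StructureError(f"cannot write {path}: {e}") from e


def transform_structure(s: Structure, rotation: np.ndarray,
                        translation: np.ndarray,
                        pre_translation: np.ndarray | None = None) -> Structure:
    """Return a copy with coords mapped x -> R(x + pre_t) + t."""
    out = s.copy()
    pre = np.zeros(3) if pre_translation is None else np.asarray(pre_translation, float)
    rot = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    for res in out.residues():
        for a in res.atoms:
            a.coord = rot @ (a.coord + pre) + t
    return out


def translate_structure(s: Structure, vec) -> Structure:
    return transform_structure(s, np.eye(3), np.asarray(vec, float))
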