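"""Membrane placement by exhaustive pseudo-energy grid search.

The protein is recentred on the centroid of its representative atoms and
oriented relative to a dummy lipid slab (normal along Z, hydrophobic
half-width 15 A by default) by enumerating rotations about X and Y and a
translation along Z.  Each orientation is scored by the transfer energy:
the sum over amino-acid residues of a depth-dependent per-residue-type
pseudo-energy (sigmoidal for most residue types, gaussian for the
interface-seeking aromatics Trp/Tyr).  The minimum-energy grid point is
the placement; residues are then labelled CORE (inside the slab), HEAD
(within the headgroup belt just beyond it) or OUTSIDE by the |z| depth of
their representative atom.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .config import PlacementConfig
from .geometry import rotation_x, rotation_y
from .structure import Residue, ResidueSelector, Structure, StructureError

log = logging.getLogger(__name__)

CORE, HEAD, OUTSIDE = "CORE", "HEAD", "OUTSIDE"


@dataclass(frozen=True)
class EzCurve:
    curve_kind: str  # "sigmoidal" | "gaussian"
    E0: float
    z_mid: float
    n: float = 0.0
    sigma: float = 0.0


class EzParameterTable:
    """Per-residue-type depth-energy curves, loaded from a delimited file."""

    def __init__(self, curves: dict[str, EzCurve]):
        from .constants import STANDARD_AA
        missing = STANDARD_AA - set(curves)
        if missing:
            raise ValueError(f"Ez table missing residue types: {sorted(missing)}")
        for aa, c in curves.items():
            if c.z_mid < 0:
                raise ValueError(f"{aa}: z_mid must be >= 0")
            if c.curve_kind == "gaussian" and c.sigma <= 0:
                raise ValueError(f"{aa}: gaussian curve needs sigma > 0")
            if c.curve_kind not in ("sigmoidal", "gaussian"):
                raise ValueError(f"{aa}: unknown curve kind {c.curve_kind!r}")
        self.curves = dict(curves)

    @classmethod
    def from_file(cls, path_or_handle) -> "EzParameterTable":
        if hasattr(path_or_handle, "read"):
            fh = path_or_handle
            rows = _read_rows(fh)
        else:
            with open(path_or_handle) as fh:
                rows = _read_rows(fh)
        return cls(rows)

    @classmethod
    def default(cls) -> "EzParameterTable":
        with resources.files("tmimpact.data").joinpath("ez_params.csv").open() as fh:
            return cls(_read_rows(fh))

    def energy(self, aa_type: str, z) -> float | np.ndarray:
        """Pseudo-energy of residue type aa_type at depth z (symmetric in z)."""
        c = self.curves.get(aa_type)
        if c is None:
            raise KeyError(f"no Ez curve for residue type {aa_type!r}")
        az = np.abs(z)
        if c.curve_kind == "sigmoidal":
            return c.E0 / (1.0 + (az / c.z_mid) ** c.n)
        return c.E0 * np.exp(-((az - c.z_mid) ** 2) / (2.0 * c.sigma ** 2))


def _read_rows(fh) -> dict[str, EzCurve]:
    curves = {}
    reader = csv.DictReader(r for r in fh if not r.lstrip().startswith("#"))
    for row in reader:
        aa = row["residue"].strip()
        curves[aa] = EzCurve(
            curve_kind=row["curve_kind"].strip(),
            E0=float(row["E0"]),
            z_mid=float(row["z_mid"]),
            n=float(row["n"]) if row.get("n") else 0.0,
            sigma=float(row["sigma"]) if row.get("sigma") else 0.0,
        )
    return curves


def ez_energy(aa_type: str, z: float, table: EzParameterTable) -> float:
    return float(table.energy(aa_type, z))


@dataclass
class MembranePlacement:
    rotation_x: float
    rotation_y: float
    z_shift: float
    transfer_energy: float
    region_of: dict[ResidueSelector, str] = field(default_factory=dict)
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_grid_points: int = 0

    @property
    def rotation(self) -> np.ndarray:
        return rotation_y(self.rotation_y) @ rotation_x(self.rotation_x)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map original coordinates into the membrane frame."""
        out = (np.asarray(coords, float) - self.centroid) @ self.rotation.T
        out[..., 2] += self.z_shift
        return out

    def depth(self, coord: np.ndarray) -> float:
        return float(abs(self.apply(np.asarray(coord, float).reshape(1, 3))[0, 2]))

    def to_dict(self) -> dict:
        return {
            "rotation_x_deg": self.rotation_x,
            "rotation_y_deg": self.rotation_y,
            "z_shift": self.z_shift,
            "transfer_energy": round(self.transfer_energy, 6),
            "n_grid_points": self.n_grid_points,
            "regions": {str(sel): reg for sel, reg in sorted(
                self.region_of.items(), key=lambda kv: (kv[0].chain_id,
                                                        kv[0].seq_id,
                                                        kv[0].insertion_code))},
        }


def _representative(res: Residue, atom_name: str):
    """Representative atom, or a backbone fallback for its depth label."""
    a = res.atom(atom_name)
    if a is not None:
        return a, True
    for name in ("CA", "N", "C", "O"):
        b = res.atom(name)
        if b is not None:
            return b, False
    heavy = res.heavy_atoms()
    return (heavy[0], False) if heavy else (None, False)


def _energy_arrays(s: Structure, table: EzParameterTable, cfg: PlacementConfig):
    """(coords, curve arrays) of amino-acid residues with representative atoms."""
    coords, kinds, e0, zmid, nexp, sig = [], [], [], [], [], []
    for res in s.residues(amino_only=True):
        a = res.atom(cfg.representative_atom)
        if a is None:
            warnings.warn(
                f"{res.label()}: missing representative atom "
                f"{cfg.representative_atom!r}; excluded from transfer energy")
            continue
        c = table.curves[res.aa_type]
        coords.append(a.coord)
        kinds.append(c.curve_kind == "gaussian")
        e0.append(c.E0)
        zmid.append(c.z_mid)
        nexp.append(c.n)
        sig.append(c.sigma if c.sigma > 0 else 1.0)
    if not coords:
        raise StructureError("no amino-acid residue has a representative atom")
    return (np.array(coords), np.array(kinds, bool), np.array(e0),
            np.array(zmid), np.array(nexp), np.array(sig))


def _energies_at(z: np.ndarray, gaussian: np.ndarray, e0, zmid, nexp, sig):
    """Vectorised per-residue energies for depth array z (last axis residues)."""
    az = np.abs(z)
    with np.errstate(over="ignore"):
        sigm = e0 / (1.0 + (az / zmid) ** nexp)
    gaus = e0 * np.exp(-((az - zmid) ** 2) / (2.0 * sig ** 2))
    return np.where(gaussian, gaus, sigm)


def recentre(s: Structure, cfg: PlacementConfig | None = None) -> Structure:
    """Translate so the centroid of representative atoms is at the origin."""
    cfg = cfg or PlacementConfig()
    cen = representative_centroid(s, cfg)
    from .structure import translate_structure
    return translate_structure(s, -cen)


def representative_centroid(s: Structure, cfg: PlacementConfig) -> np.ndarray:
    pts = [res.atom(cfg.representative_atom).coord
           for res in s.residues(amino_only=True)
           if res.atom(cfg.representative_atom) is not None]
    if not pts:
        raise StructureError(
            f"no amino-acid residue has atom {cfg.representative_atom!r}")
    return np.mean(pts, axis=0)


def transfer_energy(s: Structure, rotation_x_deg: float, rotation_y_deg: float,
                    z_shift: float, table: EzParameterTable,
                    cfg: PlacementConfig | None = None) -> float:
    """Transfer energy of an already-recentred structure at one grid point."""
    cfg = cfg or PlacementConfig()
    coords, gaussian, e0, zmid, nexp, sig = _energy_arrays(s, table, cfg)
    rot = rotation_y(rotation_y_deg) @ rotation_x(rotation_x_deg)
    z = coords @ rot.T[:, 2] + z_shift
    return float(np.sum(_energies_at(z, gaussian, e0, zmid, nexp, sig)))


def grid_axes(cfg: PlacementConfig):
    rots = np.arange(0.0, 360.0, cfg.rot_step_deg)
    n_z = int((cfg.z_max - cfg.z_min) / cfg.z_step + 1e-9) + 1
    zs = cfg.z_min + cfg.z_step * np.arange(n_z)
    return rots, zs


def place(s: Structure, table: EzParameterTable | None = None,
          cfg: PlacementConfig | None = None) -> MembranePlacement:
    """Exhaustive grid search for the minimum transfer-energy orientation.

    Ties on the minimum energy are broken deterministically towards the
    lexicographically smallest (|z_shift|, rotation_x, rotation_y).
    """
    cfg = cfg or PlacementConfig()
    cfg.validate()
    table = table or EzParameterTable.default()
    centroid = representative_centroid(s, cfg)
    coords, gaussian, e0, zmid, nexp, sig = _energy_arrays(s, table, cfg)
    coords = coords - centroid

    rots, zs = grid_axes(cfg)
    if len(rots) == 0 or len(zs) == 0:
        raise ValueError("degenerate placement grid")

    # z of every residue under each (rx, ry): assemble all rotation matrices
    rx_mats = np.stack([rotation_x(r) for r in rots])        # (R,3,3)
    ry_mats = np.stack([rotation_y(r) for r in rots])        # (R,3,3)
    # z-row of Ry@Rx for every pair: (R_y, R_x, 3)
    zrow = np.einsum("yij,xjk->yxik", ry_mats, rx_mats)[:, :, 2, :]
    z_rot = np.einsum("yxk,nk->yxn", zrow, coords)           # (Ry,Rx,n)
    z_all = z_rot[:, :, None, :] + zs[None, None, :, None]   # (Ry,Rx,Z,n)
    energies = _energies_at(z_all, gaussian, e0, zmid, nexp, sig).sum(axis=-1)

    emin = float(energies.min())
    tol = 1e-9 * max(1.0, abs(emin))
    iy, ix, iz = np.where(energies <= emin + tol)
    # deterministic tiebreak: smallest (|z|, rot_x, rot_y)
    keys = sorted(zip(np.abs(zs[iz]), rots[ix], rots[iy], iz, ix, iy))
    _, _, _, kz, kx, ky = keys[0]
    pl = MembranePlacement(
        rotation_x=float(rots[kx]),
        rotation_y=float(rots[ky]),
        z_shift=float(zs[kz]),
        transfer_energy=float(energies[ky, kx, kz]),
        centroid=centroid,
        n_grid_points=int(energies.size),
    )
    pl.region_of = classify_regions(s, pl, cfg)
    return pl


def place_brute_force(s: Structure, table: EzParameterTable | None = None,
                      cfg: PlacementConfig | None = None) -> MembranePlacement:
    """Naive triple-loop reference search (oracle for the vectorised path)."""
    cfg = cfg or PlacementConfig()
    table = table or EzParameterTable.default()
    centroid = representative_centroid(s, cfg)
    residues = [(res.aa_type, res.atom(cfg.representative_atom).coord - centroid)
                for res in s.residues(amino_only=True)
                if res.atom(cfg.representative_atom) is not None]
    rots, zs = grid_axes(cfg)
    evaluated = []
    count = 0
    for ry in rots:
        for rx in rots:
            rot = rotation_y(ry) @ rotation_x(rx)
            zbase = [float(rot[2] @ c) for _, c in residues]
            for z in zs:
                count += 1
                e = sum(ez_energy(aa, zb + z, table)
                        for (aa, _), zb in zip(residues, zbase))
                evaluated.append((e, abs(z), rx, ry, z))
    emin = min(e for e, *_ in evaluated)
    tol = 1e-9 * max(1.0, abs(emin))
    _, rx, ry, z, e = min((az, rx, ry, z, e)
                          for e, az, rx, ry, z in evaluated
                          if e <= emin + tol)
    pl = MembranePlacement(rotation_x=float(rx), rotation_y=float(ry),
                           z_shift=float(z), transfer_energy=float(e),
                           centroid=centroid, n_grid_points=count)
    pl.region_of = classify_regions(s, pl, cfg)
    return pl


def classify_regions(s: Structure, placement: MembranePlacement,
                     cfg: PlacementConfig | None = None
                     ) -> dict[ResidueSelector, str]:
    """Label every amino-acid residue CORE / HEAD / OUTSIDE by |z| depth.

    The slab boundary is inclusive to CORE (d <= half thickness) and the
    head belt half-open above it (half < d <= half + margin).
    """
    cfg = cfg or PlacementConfig()
    half = cfg.core_halfwidth
    head = half + cfg.head_margin
    out: dict[ResidueSelector, str] = {}
    for res in s.residues(amino_only=True):
        atom, is_repr = _representative(res, cfg.representative_atom)
        if atom is None:
            continue
        if not is_repr:
            log.warning("%s: representative atom missing; depth taken from %s",
                        res.label(), atom.name)
        d = placement.depth(atom.coord)
        if d <= half:
            out[res.selector] = CORE
        elif d <= head:
            out[res.selector] = HEAD
        else:
            out[res.selector] = OUTSIDE
    return out


def region_from_depth(d: float, cfg: PlacementConfig | None = None) -> str:
    cfg = cfg or PlacementConfig()
    if d <= cfg.core_halfwidth:
        return CORE
    if d <= cfg.core_halfwidth + cfg.head_margin:
        return HEAD
    return OUTSIDE


def aligned_structure(s: Structure, placement: MembranePlacement,
                      with_membrane_planes: bool = False) -> Structure:
    """Copy of s in the membrane frame (slab normal = Z, midplane at z=0)."""
    from .structure import Atom, Chain, Residue as Res, transform_structure
    out = transform_structure(s, placement.rotation,
                              np.array([0.0, 0.0, placement.z_shift]),
                              pre_translation=-placement.centroid)
    if with_membrane_planes:
        half = 15.0
        ch = Chain(chain_id="z")
        num = 1
        for zsign in (-1.0, 1.0):
            for gx in range(-4, 5):
                for gy in range(-4, 5):
                    r = Res(chain_id="z", seq_id=num, aa_type="HET", het=True,
                            name="DUM")
                    r.atoms.append(Atom(name="O", element="O",
                                        coord=np.array([4.0 * gx, 4.0 * gy,
                                                        zsign * half])))
                    ch.residues.append(r)
                    num += 1
        out.chains.append(ch)
    return out
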