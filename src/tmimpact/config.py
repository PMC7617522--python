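"""Run configuration: membrane-search geometry, feature cutoffs, repacker
choice.  Round-trips losslessly through YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PlacementConfig:
    """Geometry of the dummy-bilayer grid search.

    The slab spans |z| <= hydrophobic_thickness/2; the lipid headgroup belt
    extends head_margin beyond it.  The search enumerates rotations about X
    and Y in rot_step_deg increments over [0, 360) and z translations on the
    inclusive lattice [z_min, z_max] with step z_step: with the defaults
    that is 20 x 20 x 21 = 8,400 orientations.
    """
    hydrophobic_thickness: float = 30.0
    head_margin: float = 2.0
    rot_step_deg: float = 18.0
    z_min: float = -30.0
    z_max: float = 30.0
    z_step: float = 3.0
    representative_atom: str = "CA"

    def validate(self) -> None:
        if self.hydrophobic_thickness <= 0:
            raise ValueError("hydrophobic_thickness must be > 0")
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be < z_max")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        if self.rot_step_deg <= 0 or abs(360.0 / self.rot_step_deg
                                         - round(360.0 / self.rot_step_deg)) > 1e-9:
            raise ValueError("rot_step_deg must divide 360")

    @property
    def core_halfwidth(self) -> float:
        return self.hydrophobic_thickness / 2.0

    @property
    def n_grid_points(self) -> int:
        n_rot = round(360.0 / self.rot_step_deg)
        n_z = int((self.z_max - self.z_min) / self.z_step + 1e-9) + 1
        return n_rot * n_rot * n_z


@dataclass
class RunConfig:
    """Full pipeline configuration (placement + feature thresholds)."""
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    # contact criteria: detection cutoff = base + slack.  The slack makes
    # the criteria tolerant of modelled (non-experimental) coordinates.
    slack: float = 1.0
    hbond_base: float = 3.5
    salt_bridge_base: float = 4.0
    disulphide_base: float = 2.3
    neighbourhood_radius: float = 5.0
    buried_rsa_threshold: float = 0.09
    his_charged: bool = False
    sasa_probe: float = 1.4
    sasa_points: int = 960
    repacker: str = "internal_rotamer"  # or "external_scwrl4"
    scwrl4_path: str = ""
    single_chain: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        self.placement.validate()
        for name in ("slack", "hbond_base", "salt_bridge_base",
                     "disulphide_base", "neighbourhood_radius",
                     "buried_rsa_threshold", "sasa_probe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sasa_points < 10:
            raise ValueError("sasa_points must be >= 10")
        if self.repacker not in ("internal_rotamer", "external_scwrl4"):
            raise ValueError(f"unknown repacker {self.repacker!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pc = d.pop("placement", {})
        cfg = cls(placement=PlacementConfig(**pc), **d)
        cfg.validate()
        return cfg

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def apply_override(self, key: str, value: str) -> None:
        """Apply a dotted-key override, e.g. 'placement.z_step=1.5'."""
        obj = self
        parts = key.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        name = parts[-1]
        current = getattr(obj, name)
        if isinstance(current, bool):
            setattr(obj, name, value.lower() in ("1", "true", "yes", "on"))
        elif isinstance(current, int) and not isinstance(current, bool):
            setattr(obj, name, int(value))
        elif isinstance(current, float):
            setattr(obj, name, float(value))
        else:
            setattr(obj, name, value)
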