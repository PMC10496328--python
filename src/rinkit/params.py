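"""Bond detection thresholds and energy constants.

Every value here is a deliberate, overridable default: thresholds follow
common structural-biology practice and the energy expressions are closed
forms of distance (and orientation where defined). All fields round-trip
through a flat ``key = value`` config file and are reachable from CLI flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from rinkit.errors import InputError

POLICIES = ("all", "best-per-type", "best-overall")

BOND_TYPES = ("HBOND", "VDW", "IONIC", "PIPI", "PICATION", "HYDROPHOBIC", "CA_CONTACT")

#: Specific (chemistry-driven) bond detectors; the CA contact map is a mode switch.
SPECIFIC_BONDS = ("HBOND", "VDW", "IONIC", "PIPI", "PICATION", "HYDROPHOBIC")


@dataclass
class HBondParams:
    d_max: float = 3.5           # donor-acceptor distance gate, Angstrom
    angle_min_deg: float = 120.0  # D-H...A angle gate at H
    require_h: bool = True        # False: distance-only detection, no angle gate
    d0: float = 9.0               # well depth, kcal/mol
    r0: float = 2.8               # optimum D...A distance, Angstrom


@dataclass
class VdwParams:
    surface_tol: float = 0.5      # max d - (r_i + r_j), Angstrom
    epsilon: float = 0.1          # uniform LJ well depth, kcal/mol


@dataclass
class IonicParams:
    d_max: float = 4.5            # charged-group centroid distance gate
    coulomb_k: float = 332.0      # kcal*A/(mol*e^2)
    dielectric_slope: float = 4.0  # eps(d) = slope * d


@dataclass
class PiPiParams:
    d_max: float = 6.5
    parallel_max_deg: float = 30.0
    tshape_min_deg: float = 60.0
    e0: float = 1.5               # kcal/mol at d_ref
    d_ref: float = 4.5


@dataclass
class PiCationParams:
    d_max: float = 5.0
    alpha_max_deg: float = 45.0   # off-normal angle gate
    e0: float = 2.0
    d_ref: float = 4.0


@dataclass
class HydrophobicParams:
    d_max: float = 4.5
    e0: float = 0.6
    d_onset: float = 3.5          # distance at which the well starts to fade


@dataclass
class CaParams:
    d_max: float = 8.0


@dataclass
class BondParams:
    """The full per-bond-type threshold/energy configuration."""

    hbond: HBondParams = field(default_factory=HBondParams)
    vdw: VdwParams = field(default_factory=VdwParams)
    ionic: IonicParams = field(default_factory=IonicParams)
    pipi: PiPiParams = field(default_factory=PiPiParams)
    pication: PiCationParams = field(default_factory=PiCationParams)
    hydrophobic: HydrophobicParams = field(default_factory=HydrophobicParams)
    ca_contact: CaParams = field(default_factory=CaParams)
    seq_sep_generic: int = 3
    policy: str = "all"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for section, name in (
            (self.hbond, "hbond.d_max"), (self.ionic, "ionic.d_max"),
            (self.pipi, "pipi.d_max"), (self.pication, "pication.d_max"),
            (self.hydrophobic, "hydrophobic.d_max"), (self.ca_contact, "ca_contact.d_max"),
        ):
            if section.d_max <= 0:
                raise InputError(f"{name} must be > 0")
        if self.vdw.surface_tol <= 0:
            raise InputError("vdw.surface_tol must be > 0")
        for value, name in (
            (self.hbond.angle_min_deg, "hbond.angle_min_deg"),
            (self.pipi.parallel_max_deg, "pipi.parallel_max_deg"),
            (self.pipi.tshape_min_deg, "pipi.tshape_min_deg"),
            (self.pication.alpha_max_deg, "pication.alpha_max_deg"),
        ):
            if not 0.0 <= value <= 180.0:
                raise InputError(f"{name} must be in [0, 180]")
        if self.seq_sep_generic < 1:
            raise InputError("seq_sep_generic must be >= 1")
        if self.policy not in POLICIES:
            raise InputError(f"policy must be one of {POLICIES}")

    # -- flat key=value serialization ---------------------------------------

    def to_flat(self) -> dict[str, str]:
        flat: dict[str, str] = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                for sub in dataclasses.fields(value):
                    flat[f"{f.name}.{sub.name}"] = repr(getattr(value, sub.name))
            else:
                flat[f.name] = str(value) if not isinstance(value, str) else value
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "BondParams":
        params = cls()
        for key, raw in flat.items():
            params.set(key, raw)
        params.validate()
        return params

    def set(self, key: str, raw) -> None:
        """Set a field from its flat key (e.g. ``hbond.d_max``) and a string/typed value."""
        if "." in key:
            section_name, field_name = key.split(".", 1)
            section = getattr(self, section_name, None)
            if section is None or not dataclasses.is_dataclass(section):
                raise InputError(f"unknown config section {section_name!r}")
            if field_name not in {f.name for f in dataclasses.fields(section)}:
                raise InputError(f"unknown config key {key!r}")
            current = getattr(section, field_name)
            setattr(section, field_name, _coerce(raw, type(current), key))
        else:
            if key == "policy":
                self.policy = str(raw)
            elif key == "seq_sep_generic":
                self.seq_sep_generic = _coerce(raw, int, key)
            else:
                raise InputError(f"unknown config key {key!r}")

    def dump(self, path=None) -> str:
        text = "\n".join(f"{k} = {v}" for k, v in sorted(self.to_flat().items())) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, path) -> "BondParams":
        flat: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            flat[key] = value
        return cls.from_flat(flat)

    def fingerprint(self) -> str:
        digest = hashlib.sha256(self.dump().encode()).hexdigest()
        return digest[:12]


def _coerce(raw, target_type, key: str):
    if isinstance(raw, target_type) and not isinstance(raw, str):
        return raw
    text = str(raw).strip()
    try:
        if target_type is bool:
            if text.lower() in ("true", "1", "yes", "on"):
                return True
            if text.lower() in ("false", "0", "no", "off"):
                return False
            raise ValueError(text)
        return target_type(text)
    except ValueError as exc:
        raise InputError(f"config key {key!r}: cannot parse {raw!r} as {target_type.__name__}") from exc
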