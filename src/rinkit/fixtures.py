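"""Synthetic minimal structures with exactly realized geometric parameters.

Each fixture is a chemically labelled fragment pair (or chain) whose
named distances and angles hold by construction, so the expected detector
output is analytically forced. Fragments carry only the atoms the target
detector consults plus a CA anchor. The curated catalog covers, for every
bond type, a positive case, a distance-negative case, an angle-negative case
where the criterion is angular, and an exact-boundary case at d = d_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rinkit.errors import InputError
from rinkit.params import BondParams
from rinkit.structure import Atom, Model, Residue, Structure

FIXTURE_KINDS = (
    "HBOND_PAIR", "VDW_PAIR", "IONIC_PAIR", "PIPI_PAIR",
    "PICATION_PAIR", "HYDROPHOBIC_PAIR", "CHAIN", "CA_PAIR",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    geometry: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise InputError(f"unknown fixture kind {self.kind!r}")
        for key, value in self.geometry.items():
            if key in ("d", "pair_distance") and not 0.0 < float(value) < 100.0:
                raise InputError(f"fixture {self.kind}: {key}={value} outside (0, 100)")


def _atom(name: str, element: str, coords, serial: int = 0) -> Atom:
    return Atom(serial=serial, name=name, element=element, altloc="",
                coords=np.asarray(coords, dtype=float))


def _residue(chain: str, seq: int, name: str, atoms: list[Atom]) -> Residue:
    return Residue(chain_id=chain, seq_num=seq, icode="", name=name, atoms=atoms)


def _structure(fixture_id: str, residues_by_chain: list[tuple[str, list[Residue]]],
               model_count: int = 1) -> Structure:
    base = Model(index=1, chains=residues_by_chain)
    models = [base] + [
        Model(index=k, chains=[(c, [r.copy() for r in rs]) for c, rs in base.chains])
        for k in range(2, model_count + 1)
    ]
    return Structure(id=fixture_id, models=models, source_format="pdb")


def _hexagon(radius: float = 1.39) -> np.ndarray:
    angles = np.radians(np.arange(6) * 60.0)
    return np.stack([radius * np.cos(angles), radius * np.sin(angles),
                     np.zeros(6)], axis=1)


def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[1, 0, 0],
                     [0, math.cos(t), -math.sin(t)],
                     [0, math.sin(t), math.cos(t)]])


# -- kind builders ----------------------------------------------------------


def _hbond_pair(d: float, angle: float, model_count: int) -> Structure:
    """Backbone N-H donor vs carbonyl O acceptor with |N-O| = d and D-H...A = angle."""
    n = np.zeros(3)
    h = np.array([1.01, 0.0, 0.0])
    if angle >= 179.999:
        acc = np.array([d, 0.0, 0.0])
    else:
        phi = math.radians(angle)
        u = np.array([-math.cos(phi), math.sin(phi), 0.0])
        hu = float(h @ u)
        t = -hu + math.sqrt(hu * hu - float(h @ h) + d * d)
        acc = h + t * u
    donor = _residue("A", 1, "ALA", [
        _atom("N", "N", n), _atom("H", "H", h),
        _atom("CA", "C", [-0.8, -1.2, 0.0]),
    ])
    c_pos = acc + 1.23 * (acc - h) / np.linalg.norm(acc - h)
    acceptor = _residue("A", 2, "ALA", [
        _atom("O", "O", acc), _atom("C", "C", c_pos),
        _atom("CA", "C", c_pos + [1.5, 0.0, 0.0]),
    ])
    return _structure("hbond_pair", [("A", [donor, acceptor])], model_count)


def _leu_pair(d: float, model_count: int, fixture_id: str) -> Structure:
    """Two LEU fragments whose closest atoms (CD1-CD1) sit exactly d apart."""
    res1 = _residue("A", 1, "LEU", [
        _atom("CD1", "C", [0.0, 0.0, 0.0]), _atom("CA", "C", [-3.0, 0.0, 0.0]),
    ])
    res2 = _residue("A", 2, "LEU", [
        _atom("CD1", "C", [d, 0.0, 0.0]), _atom("CA", "C", [d + 3.0, 0.0, 0.0]),
    ])
    return _structure(fixture_id, [("A", [res1, res2])], model_count)


def _ionic_pair(d: float, model_count: int) -> Structure:
    """ARG guanidinium vs ASP carboxylate with group centroids exactly d apart."""
    # Offsets are dyadic rationals that cancel exactly in float arithmetic, so
    # the group centroids land on the requested positions with zero error.
    arg = _residue("A", 1, "ARG", [
        _atom("CZ", "C", [0.0, 0.0, 0.0]),
        _atom("NE", "N", [-1.25, 0.0, 0.0]),
        _atom("NH1", "N", [0.625, 1.125, 0.0]),
        _atom("NH2", "N", [0.625, -1.125, 0.0]),
        _atom("CA", "C", [0.0, 0.0, 2.5]),
    ])
    asp = _residue("A", 2, "ASP", [
        _atom("CG", "C", [d - 0.5, 0.0, 0.0]),
        _atom("OD1", "O", [d + 0.25, 0.9375, 0.0]),
        _atom("OD2", "O", [d + 0.25, -0.9375, 0.0]),
        _atom("CA", "C", [d, 0.0, 2.5]),
    ])
    return _structure("ionic_pair", [("A", [arg, asp])], model_count)


_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _phe_ring(chain: str, seq: int, center, rotation: np.ndarray | None = None,
              anchor_offset=(4.0, 0.0, 0.0)) -> Residue:
    center = np.asarray(center, dtype=float)
    coords = _hexagon()
    if rotation is not None:
        coords = coords @ rotation.T
    atoms = [_atom(nm, "C", center + xyz) for nm, xyz in zip(_RING_NAMES, coords)]
    atoms.append(_atom("CA", "C", center + np.asarray(anchor_offset)))
    return _residue(chain, seq, "PHE", atoms)


def _pipi_pair(d: float, gamma: float, model_count: int) -> Structure:
    """Two PHE rings: centroid distance d along z, plane angle gamma (tilt about x)."""
    ring1 = _phe_ring("A", 1, [0.0, 0.0, 0.0])
    ring2 = _phe_ring("A", 2, [0.0, 0.0, d], rotation=_rot_x(gamma))
    return _structure("pipi_pair", [("A", [ring1, ring2])], model_count)


def _pication_pair(d: float, alpha: float, model_count: int) -> Structure:
    """PHE ring at the origin; LYS NZ at spherical (d, alpha) off the ring normal."""
    ring = _phe_ring("A", 1, [0.0, 0.0, 0.0])
    a = math.radians(alpha)
    direction = np.array([math.sin(a), 0.0, math.cos(a)])
    nz = d * direction
    lys = _residue("A", 2, "LYS", [
        _atom("NZ", "N", nz), _atom("CA", "C", nz + 2.0 * direction),
    ])
    return _structure("pication_pair", [("A", [ring, lys])], model_count)


def _chain(n: int, conformation: str, model_count: int, seed: int) -> Structure:
    """Poly-ALA CA trace: ideal helix (rise 1.5 A, twist 100 deg, radius 2.3 A),
    extended (collinear CA every 3.8 A), or a seeded 3D random coil with 3.8 A
    steps and directional persistence (fills space like a compact chain)."""
    if n < 1:
        raise InputError("CHAIN fixture: need n >= 1 residues")
    if conformation not in ("helix", "extended", "coil"):
        raise InputError(f"CHAIN fixture: unknown conformation {conformation!r}")
    coords = np.zeros((n, 3))
    if conformation == "helix":
        theta = np.radians(100.0 * np.arange(n))
        coords[:, 0] = 2.3 * np.cos(theta)
        coords[:, 1] = 2.3 * np.sin(theta)
        coords[:, 2] = 1.5 * np.arange(n)
    elif conformation == "extended":
        coords[:, 0] = 3.8 * np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            direction = 0.7 * direction + rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[i] = coords[i - 1] + 3.8 * direction
    residues = [
        _residue("A", i + 1, "ALA", [_atom("CA", "C", coords[i])]) for i in range(n)
    ]
    return _structure(f"chain_{conformation}{n}", [("A", residues)], model_count)


def _ca_pair(d: float, model_count: int) -> Structure:
    """Two single-residue chains with CA atoms exactly d apart (no seq-sep gate)."""
    res_a = _residue("A", 1, "ALA", [_atom("CA", "C", [0.0, 0.0, 0.0])])
    res_b = _residue("B", 1, "ALA", [_atom("CA", "C", [d, 0.0, 0.0])])
    return _structure("ca_pair", [("A", [res_a]), ("B", [res_b])], model_count)


def make_fixture(spec: FixtureSpec) -> Structure:
    """Realize a fixture spec as a Structure (deterministic; no randomness)."""
    g = spec.geometry
    models = int(g.get("model_count", 1))
    if models < 1:
        raise InputError("model_count must be >= 1")
    if spec.kind == "HBOND_PAIR":
        return _hbond_pair(float(g["d"]), float(g.get("angle", 180.0)), models)
    if spec.kind == "VDW_PAIR":
        return _leu_pair(float(g["d"]), models, "vdw_pair")
    if spec.kind == "HYDROPHOBIC_PAIR":
        return _leu_pair(float(g["d"]), models, "hydrophobic_pair")
    if spec.kind == "IONIC_PAIR":
        return _ionic_pair(float(g["d"]), models)
    if spec.kind == "PIPI_PAIR":
        return _pipi_pair(float(g["d"]), float(g.get("gamma", 0.0)), models)
    if spec.kind == "PICATION_PAIR":
        return _pication_pair(float(g["d"]), float(g.get("alpha", 0.0)), models)
    if spec.kind == "CHAIN":
        return _chain(int(g.get("n", 10)), g.get("conformation", "helix"),
                      models, spec.seed)
    if spec.kind == "CA_PAIR":
        return _ca_pair(float(g["d"]), models)
    raise InputError(f"unknown fixture kind {spec.kind!r}")  # pragma: no cover


# -- curated catalog --------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    spec: FixtureSpec
    bond_type: str
    expected_count: int


def fixture_catalog() -> list[CatalogEntry]:
    """Positive / distance-negative / angle-negative / boundary cases per detector.

    Expected counts refer to running the matching detector with default
    :class:`BondParams` on the fixture's (single) model. Boundary distances
    are the default thresholds themselves; detection is closed so they hit.
    """
    defaults = BondParams()
    vdw_boundary = (1.70 + 1.70) + defaults.vdw.surface_tol  # C-C sigma + tol
    entries = [
        ("hbond_positive", FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 180.0}), "HBOND", 1),
        ("hbond_distance_negative", FixtureSpec("HBOND_PAIR", {"d": 4.2, "angle": 180.0}), "HBOND", 0),
        ("hbond_angle_negative", FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 100.0}), "HBOND", 0),
        ("hbond_boundary", FixtureSpec("HBOND_PAIR", {"d": defaults.hbond.d_max, "angle": 180.0}), "HBOND", 1),
        ("vdw_positive", FixtureSpec("VDW_PAIR", {"d": 3.6}), "VDW", 1),
        ("vdw_negative", FixtureSpec("VDW_PAIR", {"d": 4.2}), "VDW", 0),
        ("vdw_boundary", FixtureSpec("VDW_PAIR", {"d": vdw_boundary}), "VDW", 1),
        ("ionic_positive", FixtureSpec("IONIC_PAIR", {"d": 3.5}), "IONIC", 1),
        ("ionic_negative", FixtureSpec("IONIC_PAIR", {"d": 6.0}), "IONIC", 0),
        ("ionic_boundary", FixtureSpec("IONIC_PAIR", {"d": defaults.ionic.d_max}), "IONIC", 1),
        ("pipi_parallel_positive", FixtureSpec("PIPI_PAIR", {"d": 4.0, "gamma": 0.0}), "PIPI", 1),
        ("pipi_tshaped_positive", FixtureSpec("PIPI_PAIR", {"d": 5.0, "gamma": 90.0}), "PIPI", 1),
        ("pipi_distance_negative", FixtureSpec("PIPI_PAIR", {"d": 8.5, "gamma": 0.0}), "PIPI", 0),
        ("pipi_angle_negative", FixtureSpec("PIPI_PAIR", {"d": 5.0, "gamma": 45.0}), "PIPI", 0),
        ("pipi_boundary", FixtureSpec("PIPI_PAIR", {"d": defaults.pipi.d_max, "gamma": 0.0}), "PIPI", 1),
        ("pication_positive", FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 0.0}), "PICATION", 1),
        ("pication_tilted_positive", FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 30.0}), "PICATION", 1),
        ("pication_distance_negative", FixtureSpec("PICATION_PAIR", {"d": 6.0, "alpha": 0.0}), "PICATION", 0),
        ("pication_angle_negative", FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 60.0}), "PICATION", 0),
        ("pication_boundary", FixtureSpec("PICATION_PAIR", {"d": defaults.pication.d_max, "alpha": 0.0}), "PICATION", 1),
        ("hydrophobic_positive", FixtureSpec("HYDROPHOBIC_PAIR", {"d": 4.0}), "HYDROPHOBIC", 1),
        ("hydrophobic_negative", FixtureSpec("HYDROPHOBIC_PAIR", {"d": 6.0}), "HYDROPHOBIC", 0),
        ("hydrophobic_boundary", FixtureSpec("HYDROPHOBIC_PAIR", {"d": defaults.hydrophobic.d_max}), "HYDROPHOBIC", 1),
        # helix: |i-j| in {3, 4} stay under 8 A (i,i+5 is ~8.66 A); 7 + 6 pairs
        ("ca_helix_positive", FixtureSpec("CHAIN", {"n": 10, "conformation": "helix"}), "CA_CONTACT", 13),
        ("ca_extended_negative", FixtureSpec("CHAIN", {"n": 6, "conformation": "extended"}), "CA_CONTACT", 0),
        ("ca_boundary", FixtureSpec("CA_PAIR", {"d": defaults.ca_contact.d_max}), "CA_CONTACT", 1),
    ]
    return [CatalogEntry(name, spec, bond_type, count)
            for name, spec, bond_type, count in entries]


# -- random structures for oracle-equivalence testing -----------------------

#: Idealized local templates (name, element, offset) per residue type; rings
#: are exact regular polygons so their plane frames are well defined.
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("H", "H", (-1.2, 1.81, 0.0))],
    "ALA": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("H", "H", (-1.2, 1.81, 0.0))],
    "SER": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("OG", "O", (0.2, -2.3, 0.6)),
            ("HG", "H", (0.2, -3.1, 1.2))],
    "LEU": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("CG", "C", (0.1, -2.4, 0.6)),
            ("CD1", "C", (1.3, -3.1, 1.2)), ("CD2", "C", (-1.2, -3.1, 0.9))],
    "LYS": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("CG", "C", (0.1, -2.4, 0.6)),
            ("CD", "C", (0.2, -3.5, 1.6)), ("CE", "C", (0.3, -4.9, 1.1)),
            ("NZ", "N", (0.4, -5.9, 2.1)), ("HZ1", "H", (0.4, -6.85, 1.8))],
    "ASP": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("CG", "C", (0.1, -2.4, 0.6)),
            ("OD1", "O", (1.1, -3.1, 0.8)), ("OD2", "O", (-0.9, -2.9, 0.0))],
    "ARG": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)), ("CG", "C", (0.1, -2.4, 0.6)),
            ("NE", "N", (0.2, -3.5, 1.5)), ("CZ", "C", (0.3, -4.8, 1.2)),
            ("NH1", "N", (0.4, -5.7, 2.1)), ("NH2", "N", (0.3, -5.2, -0.1)),
            ("HE", "H", (0.2, -3.3, 2.49))],
    "PHE": [("N", "N", (-1.2, 0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.0)), ("O", "O", (2.3, 0.1, 0.3)),
            ("CB", "C", (0.0, -1.0, 1.1)),
            ("CG", "C", (1.39, -2.5, 1.1)), ("CD1", "C", (0.695, -3.7038, 1.1)),
            ("CE1", "C", (-0.695, -3.7038, 1.1)), ("CZ", "C", (-1.39, -2.5, 1.1)),
            ("CE2", "C", (-0.695, -1.2962, 1.1)), ("CD2", "C", (0.695, -1.2962, 1.1))],
}


def random_structure(n_residues: int, seed: int = 0, box: float = 22.0,
                     types: tuple[str, ...] | None = None) -> Structure:
    """A random single-model structure for oracle-equivalence testing.

    Residues are drawn from idealized templates, randomly rotated and placed
    uniformly in a cubic box (overlaps permitted, detectors do not mind).
    Deterministic for a given (n_residues, seed, box, types).
    """
    rng = np.random.default_rng(seed)
    names = types if types is not None else tuple(_TEMPLATES)
    residues: list[Residue] = []
    for i in range(n_residues):
        name = names[int(rng.integers(len(names)))]
        # uniform random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        origin = rng.uniform(0.0, box, size=3)
        atoms = [
            _atom(an, el, origin + q @ np.asarray(off), serial=len(residues) + k)
            for k, (an, el, off) in enumerate(_TEMPLATES[name])
        ]
        residues.append(_residue("A", i + 1, name, atoms))
    return _structure(f"random{n_residues}s{seed}", [("A", residues)])
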