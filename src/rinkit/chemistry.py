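"""Per-residue chemistry annotation: donors, acceptors, charges, rings, hydrophobics.

The tables below are data, not code: they can be overridden by passing
modified copies to :func:`annotate_chemistry`. Atoms named in a table but
absent from the structure are silently skipped (fragments and truncated side
chains degrade gracefully); residues with no table entry get an empty
annotation and can only take part in vdW and C-alpha contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from rinkit.structure import Atom, PreparedModel, Residue

logger = logging.getLogger("rinkit.chemistry")

STANDARD_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

#: Bondi van der Waals radii by element (Angstrom); unlisted elements default to 1.70.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_VDW_RADIUS = 1.70

#: Side-chain hydrogen-bond donor heavy atoms (the backbone N is added for all but PRO).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}

#: Side-chain acceptors (backbone O/OXT added for every residue).
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "CYS": ("SG",),
}

CATION_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "LYS": (("NZ",),),
    "ARG": (("CZ", "NH1", "NH2", "NE"),),
}

#: Doubly protonated His as a cation is plausible but pH dependent; off by default.
HIS_CATION_GROUP: tuple[str, ...] = ("CG", "ND1", "CD2", "CE1", "NE2")

ANION_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "ASP": (("CG", "OD1", "OD2"),),
    "GLU": (("CD", "OE1", "OE2"),),
}

#: The C-terminal carboxylate counts as an anion when OXT is present.
CTERM_ANION_GROUP: tuple[str, ...] = ("C", "O", "OXT")

AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

#: Apolar side-chain C/S atoms. Polar-terminal side chains (Lys, Arg) keep only
#: their membrane-proximal CB-CG(-CD) segment; Thr is excluded altogether.
HYDROPHOBIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "CYS": ("CB", "SG"),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
}

#: Max distance used to associate a hydrogen with its donor heavy atom.
H_ATTACH_MAX = 1.3


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


@dataclass
class ResidueChemistry:
    """Annotation of one residue, referencing live Atom objects."""

    donors: list[tuple[Atom, list[Atom]]] = field(default_factory=list)
    acceptors: list[Atom] = field(default_factory=list)
    cation_groups: list[list[Atom]] = field(default_factory=list)
    anion_groups: list[list[Atom]] = field(default_factory=list)
    rings: list[list[Atom]] = field(default_factory=list)
    hydrophobic_atoms: list[Atom] = field(default_factory=list)


@dataclass
class ChemistryMap:
    """Per-residue chemistry for a prepared model (indexed like its residue list)."""

    residues: list[ResidueChemistry]

    def __getitem__(self, idx: int) -> ResidueChemistry:
        return self.residues[idx]

    def __len__(self) -> int:
        return len(self.residues)


def _attached_hydrogens(res: Residue, donor: Atom) -> list[Atom]:
    return [
        a for a in res.atoms
        if a.is_hydrogen and float(np.linalg.norm(a.coords - donor.coords)) <= H_ATTACH_MAX
    ]


def _group_atoms(res: Residue, names: tuple[str, ...]) -> list[Atom] | None:
    atoms = [a for name in names if (a := res.atom(name)) is not None]
    return atoms or None


def annotate_chemistry(
    model: PreparedModel,
    his_as_cation: bool = False,
    donors: dict | None = None,
    acceptors: dict | None = None,
    cations: dict | None = None,
    anions: dict | None = None,
    rings: dict | None = None,
    hydrophobics: dict | None = None,
) -> ChemistryMap:
    """Annotate each residue of a prepared model with its interaction chemistry.

    Table overrides replace the built-in dictionaries wholesale. Rings are
    kept only when every member atom is present (a partial ring has no
    meaningful plane); all other groups keep whichever member atoms exist.
    """
    donors = SIDECHAIN_DONORS if donors is None else donors
    acceptors = SIDECHAIN_ACCEPTORS if acceptors is None else acceptors
    cations = CATION_GROUPS if cations is None else cations
    anions = ANION_GROUPS if anions is None else anions
    rings = AROMATIC_RINGS if rings is None else rings
    hydrophobics = HYDROPHOBIC_ATOMS if hydrophobics is None else hydrophobics

    annotated: list[ResidueChemistry] = []
    for res in model.residues:
        chem = ResidueChemistry()
        name = res.name
        if name in STANDARD_RESIDUES:
            donor_names = list(donors.get(name, ()))
            if name != "PRO":
                donor_names.insert(0, "N")
            for dn in donor_names:
                atom = res.atom(dn)
                if atom is not None:
                    chem.donors.append((atom, _attached_hydrogens(res, atom)))
            acceptor_names = ["O", "OXT", *acceptors.get(name, ())]
            chem.acceptors = [a for an in acceptor_names if (a := res.atom(an)) is not None]
            for group in cations.get(name, ()):
                atoms = _group_atoms(res, group)
                if atoms:
                    chem.cation_groups.append(atoms)
            if his_as_cation and name == "HIS":
                atoms = _group_atoms(res, HIS_CATION_GROUP)
                if atoms:
                    chem.cation_groups.append(atoms)
            for group in anions.get(name, ()):
                atoms = _group_atoms(res, group)
                if atoms:
                    chem.anion_groups.append(atoms)
            if res.atom("OXT") is not None:
                atoms = _group_atoms(res, CTERM_ANION_GROUP)
                if atoms:
                    chem.anion_groups.append(atoms)
            for ring_names in rings.get(name, ()):
                atoms = [res.atom(rn) for rn in ring_names]
                if all(a is not None for a in atoms):
                    chem.rings.append(atoms)  # type: ignore[arg-type]
            chem.hydrophobic_atoms = [
                a for hn in hydrophobics.get(name, ()) if (a := res.atom(hn)) is not None
            ]
        annotated.append(chem)
    return ChemistryMap(residues=annotated)


def group_centroid(atoms: list[Atom]) -> np.ndarray:
    return np.mean([a.coords for a in atoms], axis=0)
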