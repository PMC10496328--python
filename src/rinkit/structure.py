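"""Structure I/O: read PDB/mmCIF into a uniform hierarchy, prepare models, write PDB.

Parsing is delegated to Bio.PDB (fixed-width PDB and the mmCIF ``_atom_site``
category); the parsed entities are flattened into lightweight records carrying
only what interaction detection consumes. All coordinates are in Angstrom and
author numbering is used verbatim.
"""

from __future__ import annotations

import io
import logging
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from rinkit.errors import EmptyStructureError, InputError

logger = logging.getLogger("rinkit.structure")

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_ALTLOC_POLICIES = ("highest-occupancy", "first")
_MODEL_SELECTIONS = ("one-index", "all")


@dataclass
class Atom:
    """One crystallographic atom record."""

    serial: int
    name: str
    element: str
    altloc: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            logger.warning("atom %s: occupancy %g outside [0,1]; clamping", self.name, self.occupancy)
            self.occupancy = min(1.0, max(0.0, self.occupancy))

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    """A residue identified by (chain_id, seq_num, icode) with author numbering."""

    chain_id: str
    seq_num: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def ref(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seq_num, self.icode, self.name)

    @property
    def node_id(self) -> str:
        return f"{self.chain_id}:{self.seq_num}:{self.icode}:{self.name}"

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass
class Model:
    """One coordinate set (NMR model / MD snapshot)."""

    index: int  # 1-based
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)

    def residues(self) -> list[Residue]:
        return [r for _, residues in self.chains for r in residues]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Model":
        return Model(self.index, [(c, [r.copy() for r in rs]) for c, rs in self.chains])


@dataclass
class Structure:
    """A parsed structure file: one or more models."""

    id: str
    models: list[Model]
    source_format: str = "pdb"

    def model(self, index: int) -> Model:
        for m in self.models:
            if m.index == index:
                return m
        raise InputError(f"structure {self.id!r} has no model {index}")


@dataclass
class PrepOptions:
    """Model-preparation policies applied before detection."""

    altloc_policy: str = "highest-occupancy"
    include_hetero: bool = False
    strip_hydrogens: bool = False
    synthesize_backbone_h: bool = False
    model_selection: str = "one-index"

    def __post_init__(self) -> None:
        if self.altloc_policy not in _ALTLOC_POLICIES:
            raise InputError(f"altloc_policy must be one of {_ALTLOC_POLICIES}")
        if self.model_selection not in _MODEL_SELECTIONS:
            raise InputError(f"model_selection must be one of {_MODEL_SELECTIONS}")


@dataclass
class PreparedModel:
    """Flat residue/atom view of a prepared model, ready for spatial indexing.

    ``atoms`` holds (residue_index, Atom) pairs; ``coords`` is the matching
    (n, 3) coordinate array.
    """

    index: int
    residues: list[Residue]
    atoms: list[tuple[int, Atom]] = field(init=False)
    coords: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.atoms = [(i, a) for i, r in enumerate(self.residues) for a in r.atoms]
        if self.atoms:
            self.coords = np.array([a.coords for _, a in self.atoms], dtype=float)
        else:
            self.coords = np.zeros((0, 3))

    def to_model(self) -> Model:
        chains: dict[str, list[Residue]] = {}
        for r in self.residues:
            chains.setdefault(r.chain_id, []).append(r)
        return Model(self.index, list(chains.items()))


# ---------------------------------------------------------------------------
# Parsing


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("data_") or s.startswith("_atom_site.") or s.startswith("#"):
            return "mmcif"
        if s[:6].rstrip() in ("ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "TITLE",
                              "EXPDTA", "SEQRES", "CRYST1", "COMPND", "SOURCE"):
            return "pdb"
    return "pdb"


def _as_text(source) -> tuple[str, str]:
    """Return (text, id_stem) for a path, Path or raw-text source."""
    if isinstance(source, os.PathLike) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if not path.is_file():
            raise InputError(f"cannot read structure file: {path}")
        try:
            return path.read_text(), path.stem
        except OSError as exc:  # pragma: no cover - OS specific
            raise InputError(f"cannot read structure file: {path}: {exc}") from exc
    if isinstance(source, str):
        return source, "structure"
    raise InputError(f"unsupported source type: {type(source)!r}")


def _clean_pdb_text(text: str) -> str:
    """Drop malformed fixed-width ATOM/HETATM lines with a warning.

    Fails only when every coordinate line is malformed; an unparseable serial
    is tolerated (replaced with 0) since only coordinates matter downstream.
    """
    kept: list[str] = []
    atom_like = dropped = 0
    for line in text.splitlines():
        record = line[:6].rstrip()
        if record in ("ATOM", "HETATM"):
            atom_like += 1
            ok = len(line) >= 54
            if ok:
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    ok = False
            if not ok:
                dropped += 1
                logger.warning("skipping malformed PDB line: %r", line[:40])
                continue
            try:
                int(line[6:11])
            except ValueError:
                line = line[:6] + "    0" + line[11:]
        kept.append(line)
    if atom_like and dropped == atom_like:
        raise InputError("every ATOM/HETATM line in the PDB input is malformed")
    return "\n".join(kept) + "\n"


def _convert_biopdb(bio_structure, struct_id: str, fmt: str) -> Structure:
    models: list[Model] = []
    for k, bio_model in enumerate(bio_structure, start=1):
        chains: list[tuple[str, list[Residue]]] = []
        for bio_chain in bio_model:
            residues: list[Residue] = []
            for bio_res in bio_chain:
                hetfield, seq_num, icode = bio_res.id
                res = Residue(
                    chain_id=str(bio_chain.id),
                    seq_num=int(seq_num),
                    icode=icode.strip(),
                    name=bio_res.resname.strip(),
                    is_hetero=(hetfield.strip() != ""),
                )
                for bio_atom in bio_res.get_unpacked_list():
                    occ = bio_atom.get_occupancy()
                    elem = (bio_atom.element or "").strip().upper()
                    if not elem:
                        # fall back on the first alphabetic character of the name
                        elem = next((c for c in bio_atom.name if c.isalpha()), "X").upper()
                    res.atoms.append(
                        Atom(
                            serial=int(bio_atom.serial_number or 0),
                            name=bio_atom.name.strip(),
                            element=elem,
                            altloc=bio_atom.get_altloc().strip(),
                            coords=np.asarray(bio_atom.coord, dtype=float),
                            occupancy=1.0 if occ is None else float(occ),
                            is_hetero=(hetfield.strip() != ""),
                        )
                    )
                if res.atoms:
                    residues.append(res)
            residues.sort(key=lambda r: (r.seq_num, r.icode))
            if residues:
                chains.append((str(bio_chain.id), residues))
        models.append(Model(index=k, chains=chains))
    structure = Structure(id=struct_id, models=models, source_format=fmt)
    if sum(m.atom_count() for m in structure.models) == 0:
        raise EmptyStructureError(f"structure {struct_id!r} contains no atoms")
    _check_topology(structure)
    return structure


def _check_topology(structure: Structure) -> None:
    if len(structure.models) < 2:
        return
    keys0 = [r.key for r in structure.models[0].residues()]
    for m in structure.models[1:]:
        if [r.key for r in m.residues()] != keys0:
            logger.warning(
                "structure %s: model %d residue topology differs from model 1",
                structure.id, m.index,
            )
            return


def parse_structure(source, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file (path or raw text) into a :class:`Structure`.

    ``format="auto"`` sniffs mmCIF from a ``data_`` block or ``_atom_site``
    loop; anything else is treated as fixed-width PDB. Malformed PDB lines are
    skipped with a warning (Bio.PDB permissive mode); a file with zero parsable
    atoms raises :class:`EmptyStructureError`.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    text, stem = _as_text(source)
    fmt = format
    if fmt == "auto":
        fmt = _sniff_format(text)
    if fmt not in ("pdb", "mmcif"):
        raise InputError(f"unknown format {format!r}")
    if fmt == "pdb":
        text = _clean_pdb_text(text)
    handle = io.StringIO(text)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if fmt == "mmcif":
                bio = MMCIFParser(QUIET=True).get_structure(stem, handle)
            else:
                bio = PDBParser(QUIET=True, PERMISSIVE=True).get_structure(stem, handle)
        except EmptyStructureError:
            raise
        except Exception as exc:
            raise InputError(f"failed to parse {fmt} input: {exc}") from exc
    return _convert_biopdb(bio, stem, fmt)


# ---------------------------------------------------------------------------
# Writing


def _pdb_atom_name(atom: Atom) -> str:
    # Columns 13-16; single-letter elements with short names start in column 14.
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _format_atom_line(atom: Atom, res: Residue, serial: int) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    x, y, z = atom.coords
    chain = (res.chain_id or " ")[0]
    return (
        f"{record}{serial:5d} {_pdb_atom_name(atom)}{(atom.altloc or ' ')[:1]}"
        f"{res.name[:3]:>3} {chain}{res.seq_num:4d}{(res.icode or ' ')[:1]}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}          "
        f"{atom.element[:2]:>2}"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write ``structure`` as fixed-width PDB (MODEL/ENDMDL when multi-model)."""
    lines: list[str] = []
    multi = len(structure.models) > 1
    for model in structure.models:
        if multi:
            lines.append(f"MODEL {model.index:8d}")
        serial = 0
        for _, residues in model.chains:
            for res in residues:
                for atom in res.atoms:
                    serial += 1
                    if not np.all(np.isfinite(atom.coords)):
                        raise InputError("write_pdb: non-finite coordinates")
                    lines.append(_format_atom_line(atom, res, serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write PDB to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Preparation


def _collapse_altlocs(res: Residue, policy: str) -> list[Atom]:
    groups: dict[str, list[Atom]] = {}
    for a in res.atoms:
        groups.setdefault(a.name, []).append(a)
    out: list[Atom] = []
    for name, group in groups.items():
        if len(group) == 1:
            out.append(group[0])
        elif policy == "first":
            out.append(group[0])
        else:  # highest-occupancy; ties broken by file order
            out.append(max(group, key=lambda a: a.occupancy))
    return out


def _has_amide_h(res: Residue, n_atom: Atom) -> bool:
    for a in res.atoms:
        if a.is_hydrogen and float(np.linalg.norm(a.coords - n_atom.coords)) <= 1.3:
            return True
    return False


def _synthesize_backbone_h(chains: dict[str, list[Residue]]) -> None:
    """Place an amide H on each eligible backbone N at N-H = 1.01 Angstrom.

    The H lies in the peptide plane along the bisector of the C(i-1)->N and
    CA->N directions (i.e. opposite the carbonyl). Prolines, chain N-termini
    and residues that already carry an amide H are skipped.
    """
    for residues in chains.values():
        for prev, res in zip(residues, residues[1:]):
            if res.name == "PRO":
                continue
            n, ca, c_prev = res.atom("N"), res.atom("CA"), prev.atom("C")
            if n is None or ca is None or c_prev is None:
                continue
            if float(np.linalg.norm(n.coords - c_prev.coords)) > 1.8:
                continue  # chain break: treat as N-terminus
            if _has_amide_h(res, n):
                continue
            u = n.coords - c_prev.coords
            v = n.coords - ca.coords
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                continue
            direction = u / nu + v / nv
            norm = np.linalg.norm(direction)
            if norm < 1e-8:
                continue
            res.atoms.append(
                Atom(
                    serial=0,
                    name="H",
                    element="H",
                    altloc="",
                    coords=n.coords + 1.01 * direction / norm,
                    occupancy=1.0,
                )
            )


def prepare_model(model: Model | PreparedModel, options: PrepOptions) -> PreparedModel:
    """Apply preparation policies and flatten a model for detection.

    Waters are always removed; hetero residues are removed unless
    ``include_hetero``; altlocs are collapsed per policy; hydrogens are
    stripped on request; optionally a backbone amide H is synthesized.
    The operation is idempotent.
    """
    if isinstance(model, PreparedModel):
        model = model.to_model()
    chains: dict[str, list[Residue]] = {}
    for chain_id, residues in model.chains:
        kept: list[Residue] = []
        for res in residues:
            if res.is_water:
                continue
            if res.is_hetero and not options.include_hetero:
                continue
            res = res.copy()
            res.atoms = _collapse_altlocs(res, options.altloc_policy)
            for a in res.atoms:
                a.altloc = ""
            if options.strip_hydrogens:
                res.atoms = [a for a in res.atoms if not a.is_hydrogen]
            if not res.atoms:
                logger.warning("residue %s dropped: no atoms left after filtering", res.node_id)
                continue
            kept.append(res)
        if kept:
            chains.setdefault(chain_id, []).extend(kept)
    if options.synthesize_backbone_h and not options.strip_hydrogens:
        _synthesize_backbone_h(chains)
    flat = [r for residues in chains.values() for r in residues]
    flat.sort(key=lambda r: r.key)
    return PreparedModel(index=model.index, residues=flat)


def count_residues(structure: Structure, model_index: int = 1,
                   standard_only: bool = True, per_chain: bool = False):
    """Count residues in one model, overall or per chain.

    ``standard_only`` restricts the count to non-hetero, non-water residues.
    Exposed both ways because tools differ on the convention.
    """
    model = structure.model(model_index)
    counts: dict[str, int] = {}
    for chain_id, residues in model.chains:
        n = sum(
            1 for r in residues
            if not standard_only or (not r.is_hetero and not r.is_water)
        )
        counts[chain_id] = counts.get(chain_id, 0) + n
    if per_chain:
        return counts
    return sum(counts.values())
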