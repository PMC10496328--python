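"""Geometric detectors for the seven interaction types and their energies.

Each detector maps its distance gate onto closed-ball kD-tree radius queries
over the relevant atom (or pseudo-point) subset, applies the type's
orientation gates, and emits canonical undirected :class:`Contact` records.
Bond types are independent layers: the same atom pair may appear under
several types until :func:`apply_policy` filters them.

All comparisons against thresholds are closed (<=, >=): a contact at exactly
the threshold is detected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from rinkit.chemistry import ChemistryMap, group_centroid, vdw_radius
from rinkit.geometry import angle_deg, folded_angle_deg, plane_angle_deg, ring_frame
from rinkit.kdtree import EvalCounter, KdTree
from rinkit.params import BondParams, SPECIFIC_BONDS
from rinkit.structure import PreparedModel

logger = logging.getLogger("rinkit.detectors")


@dataclass
class Contact:
    """One detected interaction between two residues (canonical: res_a < res_b)."""

    bond_type: str
    idx_a: int                      # indices into the prepared model's residue list
    idx_b: int
    res_a: tuple                    # (chain, seq_num, icode, name)
    res_b: tuple
    atoms_a: tuple                  # participating atom names on each side
    atoms_b: tuple
    distance: float
    angle: float | None = None      # degrees; None for distance-only criteria
    energy: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def sort_key(self):
        return (self.idx_a, self.idx_b, self.bond_type, self.atoms_a, self.atoms_b)


def _canonical(model: PreparedModel, bond_type: str, i: int, j: int,
               atoms_i: tuple, atoms_j: tuple, distance: float,
               angle: float | None = None, extra: dict | None = None,
               roles: tuple[str, str] | None = None) -> Contact:
    extra = dict(extra or {})
    if i > j:
        i, j = j, i
        atoms_i, atoms_j = atoms_j, atoms_i
        if roles is not None:
            roles = (roles[1], roles[0])
    if roles is not None:
        extra["role_a"], extra["role_b"] = roles
    return Contact(
        bond_type=bond_type,
        idx_a=i, idx_b=j,
        res_a=model.residues[i].ref, res_b=model.residues[j].ref,
        atoms_a=atoms_i, atoms_b=atoms_j,
        distance=float(distance), angle=angle, extra=extra,
    )


# ---------------------------------------------------------------------------
# Energy closed forms


def bond_energy(contact: Contact, params: BondParams) -> float:
    """Distance/orientation-dependent interaction energy in kcal/mol.

    Negative values are favourable; every form decays to 0- as d grows.
    A missing angle in an angular form falls back to an orientation factor
    of 1.
    """
    d = contact.distance
    t = contact.bond_type
    if t == "HBOND":
        p = params.hbond
        x = p.r0 / d
        radial = p.d0 * (5.0 * x**12 - 6.0 * x**10)
        if contact.angle is None:
            logger.debug("HBOND energy without D-H...A angle: orientation factor 1")
            return radial
        return radial * math.cos(math.radians(contact.angle)) ** 4
    if t == "VDW":
        sigma = contact.extra.get("sigma")
        if sigma is None:
            raise ValueError("VDW contact lacks the sigma = r_i + r_j annotation")
        x = sigma / d
        return params.vdw.epsilon * (x**12 - 2.0 * x**6)
    if t == "IONIC":
        p = params.ionic
        return p.coulomb_k * (-1.0) / (p.dielectric_slope * d * d)
    if t == "PIPI":
        p = params.pipi
        return -p.e0 * (p.d_ref / d) ** 2
    if t == "PICATION":
        p = params.pication
        if contact.angle is None:
            logger.warning("PICATION energy without off-normal angle: orientation factor 1")
            factor = 1.0
        else:
            factor = math.cos(math.radians(contact.angle)) ** 2
        return -p.e0 * factor * (p.d_ref / d) ** 2
    if t == "HYDROPHOBIC":
        p = params.hydrophobic
        span = p.d_max - p.d_onset
        raw = -p.e0 * (1.0 - (d - p.d_onset) / span) if span > 0 else -p.e0
        return min(0.0, max(-p.e0, raw))
    if t == "CA_CONTACT":
        return 0.0
    raise ValueError(f"unknown bond type {t!r}")


def _energize(contacts: list[Contact], params: BondParams) -> list[Contact]:
    for c in contacts:
        c.energy = float(bond_energy(c, params))
    return contacts


# ---------------------------------------------------------------------------
# Detectors


def detect_hydrogen_bonds(model: PreparedModel, chem: ChemistryMap,
                          params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """Donor-acceptor pairs with |D-A| <= d_max; when ``require_h`` the donor
    must carry a hydrogen and the best D-H...A angle must be >= angle_min."""
    p = params.hbond
    acceptors = [(ri, a) for ri in range(len(model.residues)) for a in chem[ri].acceptors]
    if not acceptors:
        return []
    tree = KdTree.build((k, a.coords) for k, (_, a) in enumerate(acceptors))
    out: list[Contact] = []
    for ri in range(len(model.residues)):
        for donor, hydrogens in chem[ri].donors:
            if p.require_h and not hydrogens:
                continue
            for k in tree.query_radius(donor.coords, p.d_max, counter):
                rj, acc = acceptors[k]
                if rj == ri:
                    continue
                d = float(np.linalg.norm(acc.coords - donor.coords))
                best_angle = None
                best_h = None
                if p.require_h:
                    for h in hydrogens:
                        theta = angle_deg(donor.coords, h.coords, acc.coords)
                        if best_angle is None or theta > best_angle:
                            best_angle, best_h = theta, h
                    if best_angle is None or best_angle < p.angle_min_deg:
                        continue
                atoms_d = (donor.name,) if best_h is None else (donor.name, best_h.name)
                out.append(_canonical(
                    model, "HBOND", ri, rj, atoms_d, (acc.name,), d,
                    angle=best_angle, roles=("donor", "acceptor"),
                ))
    return _energize(out, params)


def detect_vdw(model: PreparedModel, chem: ChemistryMap,
               params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """Heavy-atom pairs of distinct residues with d <= r_i + r_j + surface_tol."""
    tol = params.vdw.surface_tol
    heavy = [(ri, a) for ri, a in model.atoms if not a.is_hydrogen]
    if not heavy:
        return []
    radii = [vdw_radius(a.element) for _, a in heavy]
    reach = 2.0 * max(radii) + tol
    tree = KdTree.build((k, a.coords) for k, (_, a) in enumerate(heavy))
    out: list[Contact] = []
    for k1, (ri, a1) in enumerate(heavy):
        for k2 in tree.query_radius(a1.coords, reach, counter):
            if k2 <= k1:
                continue
            rj, a2 = heavy[k2]
            if rj == ri:
                continue
            sigma = radii[k1] + radii[k2]
            d = float(np.linalg.norm(a2.coords - a1.coords))
            if d <= sigma + tol:
                out.append(_canonical(
                    model, "VDW", ri, rj, (a1.name,), (a2.name,), d,
                    extra={"sigma": sigma},
                ))
    return _energize(out, params)


def detect_ionic(model: PreparedModel, chem: ChemistryMap,
                 params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """Cation-/anion-group centroid pairs within d_max (formal charges +-1)."""
    p = params.ionic
    cations = [(ri, g, group_centroid(g)) for ri in range(len(model.residues))
               for g in chem[ri].cation_groups]
    anions = [(ri, g, group_centroid(g)) for ri in range(len(model.residues))
              for g in chem[ri].anion_groups]
    if not cations or not anions:
        return []
    tree = KdTree.build((k, c) for k, (_, _, c) in enumerate(anions))
    out: list[Contact] = []
    for ri, cat_atoms, cat_c in cations:
        for k in tree.query_radius(cat_c, p.d_max, counter):
            rj, an_atoms, an_c = anions[k]
            if rj == ri:
                continue
            d = float(np.linalg.norm(an_c - cat_c))
            out.append(_canonical(
                model, "IONIC", ri, rj,
                tuple(a.name for a in cat_atoms), tuple(a.name for a in an_atoms),
                d, roles=("cation", "anion"),
            ))
    return _energize(out, params)


def _ring_frames(model: PreparedModel, chem: ChemistryMap):
    frames = []
    for ri in range(len(model.residues)):
        for atoms in chem[ri].rings:
            frames.append((ri, atoms, ring_frame([a.coords for a in atoms],
                                                 tuple(a.name for a in atoms))))
    return frames


def detect_pipi(model: PreparedModel, chem: ChemistryMap,
                params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """Aromatic ring pairs: centroids within d_max, plane angle parallel or T-shaped."""
    p = params.pipi
    frames = _ring_frames(model, chem)
    if len(frames) < 2:
        return []
    tree = KdTree.build((k, f.centroid) for k, (_, _, f) in enumerate(frames))
    out: list[Contact] = []
    for k1, (ri, atoms_i, f1) in enumerate(frames):
        for k2 in tree.query_radius(f1.centroid, p.d_max, counter):
            if k2 <= k1:
                continue
            rj, atoms_j, f2 = frames[k2]
            if rj == ri:
                continue
            gamma = plane_angle_deg(f1.normal, f2.normal)
            if not (gamma <= p.parallel_max_deg or gamma >= p.tshape_min_deg):
                continue
            d = float(np.linalg.norm(f2.centroid - f1.centroid))
            stack = "parallel" if gamma <= p.parallel_max_deg else "t-shaped"
            out.append(_canonical(
                model, "PIPI", ri, rj,
                tuple(a.name for a in atoms_i), tuple(a.name for a in atoms_j),
                d, angle=gamma, extra={"stack": stack},
            ))
    return _energize(out, params)


def detect_pication(model: PreparedModel, chem: ChemistryMap,
                    params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """Ring/cation-group pairs within d_max with off-normal angle <= alpha_max."""
    p = params.pication
    frames = _ring_frames(model, chem)
    cations = [(ri, g, group_centroid(g)) for ri in range(len(model.residues))
               for g in chem[ri].cation_groups]
    if not frames or not cations:
        return []
    tree = KdTree.build((k, c) for k, (_, _, c) in enumerate(cations))
    out: list[Contact] = []
    for ri, ring_atoms, frame in frames:
        for k in tree.query_radius(frame.centroid, p.d_max, counter):
            rj, cat_atoms, cat_c = cations[k]
            if rj == ri:
                continue
            offset = cat_c - frame.centroid
            alpha = folded_angle_deg(frame.normal, offset)
            if alpha > p.alpha_max_deg:
                continue
            d = float(np.linalg.norm(offset))
            out.append(_canonical(
                model, "PICATION", ri, rj,
                tuple(a.name for a in ring_atoms), tuple(a.name for a in cat_atoms),
                d, angle=alpha, roles=("ring", "cation"),
            ))
    return _energize(out, params)


def detect_hydrophobic(model: PreparedModel, chem: ChemistryMap,
                       params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """One contact per residue pair whose closest hydrophobic atoms are within d_max."""
    p = params.hydrophobic
    atoms = [(ri, a) for ri in range(len(model.residues))
             for a in chem[ri].hydrophobic_atoms]
    if len(atoms) < 2:
        return []
    tree = KdTree.build((k, a.coords) for k, (_, a) in enumerate(atoms))
    best: dict[tuple[int, int], tuple[float, str, str]] = {}
    for k1, (ri, a1) in enumerate(atoms):
        for k2 in tree.query_radius(a1.coords, p.d_max, counter):
            if k2 <= k1:
                continue
            rj, a2 = atoms[k2]
            if rj == ri:
                continue
            d = float(np.linalg.norm(a2.coords - a1.coords))
            if d > p.d_max:
                continue
            (i, ai), (j, aj) = sorted(((ri, a1.name), (rj, a2.name)))
            cand = (d, ai, aj)
            if (i, j) not in best or cand < best[(i, j)]:
                best[(i, j)] = cand
    out = [
        _canonical(model, "HYDROPHOBIC", i, j, (ai,), (aj,), d)
        for (i, j), (d, ai, aj) in sorted(best.items())
    ]
    return _energize(out, params)


def detect_calpha_contacts(model: PreparedModel, chem: ChemistryMap,
                           params: BondParams, counter: EvalCounter | None = None) -> list[Contact]:
    """C-alpha pairs within d_max; same-chain pairs need |seq_i - seq_j| >= seq_sep."""
    p = params.ca_contact
    cas = []
    for ri, res in enumerate(model.residues):
        ca = res.atom("CA")
        if ca is None:
            logger.warning("residue %s has no CA atom; skipped in contact map", res.node_id)
            continue
        cas.append((ri, ca))
    if len(cas) < 2:
        return []
    tree = KdTree.build((k, ca.coords) for k, (_, ca) in enumerate(cas))
    out: list[Contact] = []
    for k1, (ri, ca1) in enumerate(cas):
        res_i = model.residues[ri]
        for k2 in tree.query_radius(ca1.coords, p.d_max, counter):
            if k2 <= k1:
                continue
            rj, ca2 = cas[k2]
            res_j = model.residues[rj]
            if res_i.chain_id == res_j.chain_id and \
                    abs(res_i.seq_num - res_j.seq_num) < params.seq_sep_generic:
                continue
            d = float(np.linalg.norm(ca2.coords - ca1.coords))
            out.append(_canonical(model, "CA_CONTACT", ri, rj, ("CA",), ("CA",), d))
    return _energize(out, params)


DETECTORS = {
    "HBOND": detect_hydrogen_bonds,
    "VDW": detect_vdw,
    "IONIC": detect_ionic,
    "PIPI": detect_pipi,
    "PICATION": detect_pication,
    "HYDROPHOBIC": detect_hydrophobic,
    "CA_CONTACT": detect_calpha_contacts,
}


def detect_contacts(model: PreparedModel, chem: ChemistryMap, params: BondParams,
                    which=SPECIFIC_BONDS, counter: EvalCounter | None = None) -> list[Contact]:
    """Run the selected detectors, pool their contacts and apply the edge policy."""
    contacts: list[Contact] = []
    for bond_type in which:
        contacts.extend(DETECTORS[bond_type](model, chem, params, counter))
    contacts = apply_policy(contacts, params.policy)
    return sorted(contacts, key=lambda c: c.sort_key)


def apply_policy(contacts: list[Contact], policy: str) -> list[Contact]:
    """Filter multi-edges per residue pair: keep all, the best per type, or the
    single best overall (ties: smallest distance, then atom names)."""
    if policy == "all":
        return list(contacts)
    if policy not in ("best-per-type", "best-overall"):
        raise ValueError(f"unknown policy {policy!r}")
    best: dict[tuple, Contact] = {}
    for c in contacts:
        key = (c.idx_a, c.idx_b, c.bond_type) if policy == "best-per-type" else (c.idx_a, c.idx_b)
        rank = (c.energy, c.distance, c.atoms_a, c.atoms_b)
        held = best.get(key)
        if held is None or rank < (held.energy, held.distance, held.atoms_a, held.atoms_b):
            best[key] = c
    return sorted(best.values(), key=lambda c: c.sort_key)
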