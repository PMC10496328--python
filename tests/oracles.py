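"""Independent brute-force reference implementations used to cross-check the
kD-tree-backed detectors. Everything here is a plain all-pairs scan written
directly from the detection criteria; it deliberately shares no code path
with rinkit.detectors or rinkit.kdtree (chemistry annotation tables are data
and are shared)."""

from __future__ import annotations

import math

import numpy as np

from rinkit.chemistry import vdw_radius


def dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def brute_radius(points, center, r):
    """Exhaustive closed-ball scan over (id, coords) pairs."""
    center = np.asarray(center, float)
    return sorted(pid for pid, c in points if dist(c, center) <= r)


def brute_nearest(points, center):
    center = np.asarray(center, float)
    return min(((dist(c, center), pid) for pid, c in points))


def _angle_at(b, a, c) -> float:
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _plane_normal(coords) -> np.ndarray:
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=0)
    # smallest-eigenvalue direction of the covariance: least-squares plane normal
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    return evecs[:, 0]


def _fold90(a, b) -> float:
    cosv = abs(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(max(0.0, min(1.0, cosv))))


def _key(model, i, j, atoms_i, atoms_j):
    if i > j:
        i, j, atoms_i, atoms_j = j, i, atoms_j, atoms_i
    return (i, j, tuple(atoms_i), tuple(atoms_j))


def brute_hbond(model, chem, params):
    p = params.hbond
    found = set()
    n = len(model.residues)
    for ri in range(n):
        for donor, hydrogens in chem[ri].donors:
            if p.require_h and not hydrogens:
                continue
            for rj in range(n):
                if rj == ri:
                    continue
                for acc in chem[rj].acceptors:
                    if dist(donor.coords, acc.coords) > p.d_max:
                        continue
                    if p.require_h:
                        angles = [(_angle_at(h.coords, donor.coords, acc.coords), h.name)
                                  for h in hydrogens]
                        best, h_name = max(angles)
                        if best < p.angle_min_deg:
                            continue
                        atoms_d = (donor.name, h_name)
                    else:
                        atoms_d = (donor.name,)
                    found.add(_key(model, ri, rj, atoms_d, (acc.name,)))
    return found


def brute_vdw(model, chem, params):
    tol = params.vdw.surface_tol
    heavy = [(ri, a) for ri, a in model.atoms if not a.is_hydrogen]
    found = set()
    for x, (ri, a1) in enumerate(heavy):
        for rj, a2 in heavy[x + 1:]:
            if ri == rj:
                continue
            sigma = vdw_radius(a1.element) + vdw_radius(a2.element)
            if dist(a1.coords, a2.coords) <= sigma + tol:
                found.add(_key(model, ri, rj, (a1.name,), (a2.name,)))
    return found


def _groups(chem, attr):
    out = []
    for ri in range(len(chem)):
        for g in getattr(chem[ri], attr):
            out.append((ri, g, np.mean([a.coords for a in g], axis=0)))
    return out


def brute_ionic(model, chem, params):
    found = set()
    for ri, cat, cc in _groups(chem, "cation_groups"):
        for rj, an, ac in _groups(chem, "anion_groups"):
            if ri == rj:
                continue
            if dist(cc, ac) <= params.ionic.d_max:
                found.add(_key(model, ri, rj,
                               tuple(a.name for a in cat), tuple(a.name for a in an)))
    return found


def _rings(chem):
    out = []
    for ri in range(len(chem)):
        for atoms in chem[ri].rings:
            coords = np.array([a.coords for a in atoms])
            out.append((ri, tuple(a.name for a in atoms),
                        coords.mean(axis=0), _plane_normal(coords)))
    return out


def brute_pipi(model, chem, params):
    p = params.pipi
    rings = _rings(chem)
    found = set()
    for x, (ri, names_i, ci, ni) in enumerate(rings):
        for rj, names_j, cj, nj in rings[x + 1:]:
            if ri == rj:
                continue
            if dist(ci, cj) > p.d_max:
                continue
            gamma = _fold90(ni, nj)
            if gamma <= p.parallel_max_deg or gamma >= p.tshape_min_deg:
                found.add(_key(model, ri, rj, names_i, names_j))
    return found


def brute_pication(model, chem, params):
    p = params.pication
    found = set()
    for ri, names_i, ci, ni in _rings(chem):
        for rj, cat, cc in _groups(chem, "cation_groups"):
            if ri == rj:
                continue
            if dist(ci, cc) > p.d_max:
                continue
            if _fold90(ni, cc - ci) > p.alpha_max_deg:
                continue
            found.add(_key(model, ri, rj, names_i, tuple(a.name for a in cat)))
    return found


def brute_hydrophobic(model, chem, params):
    p = params.hydrophobic
    atoms = [(ri, a) for ri in range(len(model.residues))
             for a in chem[ri].hydrophobic_atoms]
    best: dict[tuple[int, int], tuple[float, str, str]] = {}
    for x, (ri, a1) in enumerate(atoms):
        for rj, a2 in atoms[x + 1:]:
            if ri == rj:
                continue
            d = dist(a1.coords, a2.coords)
            if d > p.d_max:
                continue
            (i, ai), (j, aj) = sorted(((ri, a1.name), (rj, a2.name)))
            if (i, j) not in best or (d, ai, aj) < best[(i, j)]:
                best[(i, j)] = (d, ai, aj)
    return {(i, j, (ai,), (aj,)) for (i, j), (d, ai, aj) in best.items()}


def brute_ca(model, chem, params):
    found = set()
    residues = model.residues
    for i, res_i in enumerate(residues):
        ca_i = res_i.atom("CA")
        if ca_i is None:
            continue
        for j in range(i + 1, len(residues)):
            res_j = residues[j]
            ca_j = res_j.atom("CA")
            if ca_j is None:
                continue
            if res_i.chain_id == res_j.chain_id and \
                    abs(res_i.seq_num - res_j.seq_num) < params.seq_sep_generic:
                continue
            if dist(ca_i.coords, ca_j.coords) <= params.ca_contact.d_max:
                found.add((i, j, ("CA",), ("CA",)))
    return found


BRUTE = {
    "HBOND": brute_hbond,
    "VDW": brute_vdw,
    "IONIC": brute_ionic,
    "PIPI": brute_pipi,
    "PICATION": brute_pication,
    "HYDROPHOBIC": brute_hydrophobic,
    "CA_CONTACT": brute_ca,
}


def contact_keys(contacts):
    """Comparable key set for detector output."""
    return {(c.idx_a, c.idx_b, c.atoms_a, c.atoms_b) for c in contacts}


def brute_betweenness_ratio(graph):
    """Paper-definition betweenness by exhaustive shortest-path enumeration."""
    import itertools

    import networkx as nx

    simple = nx.Graph(graph)
    nodes = list(simple.nodes)
    all_paths = []
    for s, t in itertools.combinations(nodes, 2):
        try:
            all_paths.extend(list(nx.all_shortest_paths(simple, s, t)))
        except nx.NetworkXNoPath:
            continue
    total = len(all_paths)
    values = {}
    for v in nodes:
        through = sum(1 for path in all_paths if v in path[1:-1])
        values[v] = through / total if total else 0.0
    return values
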