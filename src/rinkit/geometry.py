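"""Primitive 3D measurements: angles and aromatic-ring planes.

Angles are degrees at the interface, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rinkit.errors import DegenerateRingError, RinkitError


@dataclass
class RingFrame:
    """Best-fit plane of a ring: centroid, unit normal, member atom ids."""

    centroid: np.ndarray
    normal: np.ndarray
    atom_ids: tuple = ()


def angle_deg(a, b, c) -> float:
    """Interior angle at vertex ``b`` of the triple (a, b, c), in [0, 180] degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise RinkitError("angle_deg: zero-length arm")
    cosine = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosine)))


def ring_frame(coords, atom_ids: tuple = ()) -> RingFrame:
    """Centroid and least-squares plane normal of >= 3 non-collinear points.

    The normal is the direction of least variance of the centered coordinates
    (SVD); its sign is fixed to positive z-component (ties: positive y, then x).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise RinkitError("ring_frame: need >= 3 points in 3D")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(float(s[0]), 1e-12)
    if float(s[1]) / scale < 1e-7:
        raise DegenerateRingError("ring_frame: points are collinear")
    normal = vt[2]
    for k in (2, 1, 0):
        if normal[k] > 1e-9:
            break
        if normal[k] < -1e-9:
            normal = -normal
            break
    normal = normal / np.linalg.norm(normal)
    return RingFrame(centroid=centroid, normal=normal, atom_ids=tuple(atom_ids))


def _as_unit(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    norm = float(np.linalg.norm(n))
    if abs(norm - 1.0) > 1e-6:
        raise RinkitError("plane_angle_deg: input is not a unit vector")
    return n / norm


def plane_angle_deg(n1, n2) -> float:
    """Acute angle between two planes given their unit normals, in [0, 90]."""
    u = _as_unit(n1)
    v = _as_unit(n2)
    cosine = float(np.clip(abs(u @ v), 0.0, 1.0))
    return float(np.degrees(np.arccos(cosine)))


def folded_angle_deg(n, v) -> float:
    """Angle between a plane normal and a direction, folded to [0, 90] degrees."""
    n = np.asarray(n, dtype=float)
    v = np.asarray(v, dtype=float)
    nn = np.linalg.norm(n)
    nv = np.linalg.norm(v)
    if nn == 0 or nv == 0:
        raise RinkitError("folded_angle_deg: zero-length vector")
    cosine = float(np.clip(abs(n @ v) / (nn * nv), 0.0, 1.0))
    return float(np.degrees(np.arccos(cosine)))
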