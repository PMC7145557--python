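"""Geometric descriptors of hairpin conformations.

The classification angle xi is measured between the bulged U40, the
A43-U66 base pair and the C45-G64 base pair of the GAUC/GAUC helix:
compact M1-like folds give small xi (around 30 degrees), M2-like folds
with the U40.A43-U66 triplet give xi near 90 degrees, and extended
structures exceed 100 degrees.  The U44-A65-U63 angle reports whether
the gatekeeper uridine U63 points into or away from the major groove.

Reference points are base-ring centroids (and midpoints of the two
centroids for a base pair); the alternative C1'-C1' midpoint convention
can be obtained by passing a custom reference function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import chemdata
from .structure import Conformation, Residue, StructureError, heavy_atoms


@dataclass(frozen=True)
class AngleSpec:
    """Residue numbers entering the xi and U63 angles (wild-type defaults)."""

    apex_pair: tuple[int, int] = (43, 66)
    distal_pair: tuple[int, int] = (45, 64)
    probe: int = 40
    u63_triplet: tuple[int, int, int] = (44, 65, 63)

    def __post_init__(self) -> None:
        for role in (self.apex_pair, self.distal_pair, self.u63_triplet):
            if len(set(role)) != len(role):
                raise ValueError("residue numbers within a role must be distinct")


def base_centroid(res: Residue) -> np.ndarray:
    """Unweighted centroid of the base-ring heavy atoms."""
    if res.name not in chemdata.RNA_BASES:
        raise StructureError(f"residue {res.name}{res.number} is not a standard nucleotide")
    names = chemdata.ring_atom_names(res.name)
    missing = [n for n in names if not res.has_atom(n)]
    if missing:
        raise StructureError(
            f"residue {res.name}{res.number}: missing ring atoms {missing}")
    return res.coords(names).mean(axis=0)


def base_plane_normal(res: Residue) -> np.ndarray:
    """Unit normal of the least-squares plane through the base ring."""
    pts = res.coords(chemdata.ring_atom_names(res.name))
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _angle_at(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Angle p-vertex-q in degrees, via atan2 for stability near 0/180."""
    u = p - vertex
    v = q - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise StructureError("degenerate angle geometry: vertex coincides with endpoint")
    return math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)), float(np.dot(u, v))))


def xi_angle(conf: Conformation, spec: AngleSpec = AngleSpec()) -> float:
    """Classification angle xi in degrees, in [0, 180].

    Vertex: midpoint of the apex-pair base centroids (A43-U66).
    Measured between the probe base centroid (U40) and the midpoint of
    the distal-pair centroids (C45-G64).
    """
    apex = np.mean([base_centroid(conf.residue(n)) for n in spec.apex_pair], axis=0)
    distal = np.mean([base_centroid(conf.residue(n)) for n in spec.distal_pair], axis=0)
    probe = base_centroid(conf.residue(spec.probe))
    return _angle_at(apex, probe, distal)


def u63_angle(conf: Conformation, spec: AngleSpec = AngleSpec()) -> float:
    """U44-A65-U63 angle in degrees (vertex at the A65 base centroid)."""
    a, vertex, b = spec.u63_triplet
    return _angle_at(base_centroid(conf.residue(vertex)),
                     base_centroid(conf.residue(a)),
                     base_centroid(conf.residue(b)))


def radius_of_gyration(conf: Conformation, selection=None,
                       mass_weighted: bool = False) -> float:
    """Radius of gyration in Angstrom (default: heavy atoms, unweighted)."""
    pairs = [(r, a) for r, a in conf.atoms() if (selection or heavy_atoms)(r, a)]
    if not pairs:
        raise StructureError("empty selection for radius of gyration")
    xyz = np.array([a.position for _, a in pairs])
    if mass_weighted:
        w = np.array([chemdata.ATOMIC_MASSES.get(a.element, 12.0) for _, a in pairs])
    else:
        w = np.ones(len(pairs))
    center = np.average(xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((xyz - center) ** 2, axis=1), weights=w)))


def _paired_coords(a: Conformation, b: Conformation, selection
                   ) -> tuple[np.ndarray, np.ndarray]:
    sel = selection or heavy_atoms
    map_a = {(r.number, at.name): at.position for r, at in a.atoms() if sel(r, at)}
    map_b = {(r.number, at.name): at.position for r, at in b.atoms() if sel(r, at)}
    common = sorted(set(map_a) & set(map_b))
    unpaired = sorted(set(map_a) ^ set(map_b))
    if unpaired and len(common) == 0:
        raise StructureError(f"no paired atoms; unpaired: {unpaired[:10]}")
    if len(common) < 3:
        raise StructureError("fewer than 3 paired atoms for superposition")
    return (np.array([map_a[k] for k in common]),
            np.array([map_b[k] for k in common]))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing |R P + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose_rmsd(a: Conformation, b: Conformation, selection=None
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of a onto b.

    Atoms are paired 1:1 by (residue number, atom name).  Returns
    (rmsd, rotation, translation) with det(rotation) = +1.
    """
    P, Q = _paired_coords(a, b, selection)
    R, t = kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return rmsd, R, t
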