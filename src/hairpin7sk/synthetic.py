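"""Deterministic, seeded generators for every fixture the pipeline needs.

The hairpin builder assembles an idealized A-form-like stack (twist
32.7 degrees, rise 2.81 A) for the paired regions of the 37-70 window
(lower stem 37-39/68-70, GAUC/GAUC helix 42-45/64-67, upper stem
46-48/60-62, an arc for the 49-59 loop) and then places the bulged
uridines U40, U41 and U63 according to a family template:

* M1: U40 joins C45-G64 (triplet T1) and U41 joins A43-U66 (T3); the
  classification angle lands near 30 degrees and U63 is buried.
* M2: U40 joins A43-U66 on its Hoogsteen edge (T2, xi near 90); U41 is
  extruded and U63 points out of the groove.
* M2STAR: as M2 but U63 forms the U63.U44-A65 triplet.
* E: all three uridines extruded, no triplets, xi above 100 degrees.

Triplet and base-pair contacts are realized by numerically superposing
ideal base templates so that the planted donor-acceptor distances are
close to 2.8 A; backbones are threaded through the base anchors with
near-ideal covalent bond lengths.  Fixtures are geometrically
plausible but NOT energy minimized: they exist to exercise the
classification, contact and interface machinery with known ground
truth, not to model RNA physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import chemdata
from .ktn import Minimum, TransitionNetwork, TransitionStateRec
from .structure import Atom, Conformation, Ensemble, Residue, StructureError

ARM_SEQUENCE = "GKKKHRRRPSKKKRHWK"

#: paired regions of the hairpin window, bottom to top
PAIR_SCHEME = [(37, 70), (38, 69), (39, 68), (42, 67), (43, 66),
               (44, 65), (45, 64), (46, 62), (47, 61), (48, 60)]
BULGES = (40, 41, 63)
LOOP = tuple(range(49, 60))

TWIST_DEG = 32.7
RISE = 2.81
#: base-pair displacement off the helix axis (local x, A); winding the
#: pairs around the axis is what opens the deep A-form major groove
X_DISPLACEMENT = -4.4

_WT = {
    37: "C", 38: "C", 39: "A", 40: "U", 41: "U", 42: "G", 43: "A",
    44: "U", 45: "C", 46: "G", 47: "C", 48: "A", 49: "G", 50: "A",
    51: "U", 52: "U", 53: "U", 54: "C", 55: "G", 56: "A", 57: "U",
    58: "C", 59: "C", 60: "U", 61: "G", 62: "C", 63: "U", 64: "G",
    65: "A", 66: "U", 67: "C", 68: "U", 69: "G", 70: "G",
}


def wild_type_sequence() -> str:
    """The default 34-nt sequence of the 37-70 window, 5' to 3'."""
    return "".join(_WT[n] for n in range(37, 71))


@dataclass(frozen=True)
class FamilyTemplate:
    name: str
    family: str           # classification label the fixture realizes
    target_xi: float      # degrees
    triplets: tuple[str, ...]
    u63_mode: str         # "in" or "out"


TEMPLATES = {
    "M1": FamilyTemplate("M1", "M1", 30.0, ("T1", "T3"), "in"),
    "M2": FamilyTemplate("M2", "M2", 90.0, ("T2",), "out"),
    "M2STAR": FamilyTemplate("M2STAR", "M2STAR", 90.0, ("T2", "M2STAR"), "in"),
    "E": FamilyTemplate("E", "E", 150.0, (), "out"),
}


@dataclass
class PlantedTruth:
    kind: str  # family / composition / funnel / pose
    payload: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "payload": self.payload,
                           "seed": self.seed}, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(d["kind"], d["payload"], d["seed"])


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


# ---------------------------------------------------------------------------
# rigid placement helpers
# ---------------------------------------------------------------------------

def _template_arrays(base: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    tmpl = chemdata.base_template(base)
    names = list(tmpl)
    coords = np.array([tmpl[n] for n in names])
    ring = chemdata.ring_atom_names(base)
    rc = np.array([tmpl[n] for n in ring]).mean(axis=0)
    return names, coords, rc


def _orthonormal_from(x: np.ndarray, z_hint: np.ndarray) -> np.ndarray:
    x = x / np.linalg.norm(x)
    z = z_hint - np.dot(z_hint, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        z = np.array([0.0, 0.0, 1.0]) - x * x[2]
        nz = np.linalg.norm(z)
    z = z / nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _place_base_at(base: str, centroid: np.ndarray, gly_toward: np.ndarray,
                   normal: np.ndarray) -> dict[str, np.ndarray]:
    """Place an ideal base with its ring centroid at ``centroid``, its
    plane normal along ``normal`` and C1' pointing toward ``gly_toward``."""
    names, coords, rc = _template_arrays(base)
    tmpl = chemdata.base_template(base)
    v_t = tmpl["C1'"] - rc
    frame_t = _orthonormal_from(v_t, np.array([0.0, 0.0, 1.0]))
    v_g = np.asarray(gly_toward, dtype=float) - centroid
    frame_g = _orthonormal_from(v_g, np.asarray(normal, dtype=float))
    R = frame_g @ frame_t.T
    placed = (coords - rc) @ R.T + centroid
    return dict(zip(names, placed))


# Watson-Crick (and wobble) donor-acceptor targets per ordered base pair
_WC_TARGETS = {
    ("A", "U"): [("N1", "N3", 2.82), ("N6", "O4", 2.86)],
    ("G", "C"): [("O6", "N4", 2.88), ("N1", "N3", 2.88), ("N2", "O2", 2.86)],
    ("G", "U"): [("O6", "N3", 2.83), ("N1", "O2", 2.83)],
}
for (a, b), t in list(_WC_TARGETS.items()):
    _WC_TARGETS[(b, a)] = [(y, x, d) for x, y, d in t]


def wc_compatible(a: str, b: str) -> bool:
    return (a, b) in _WC_TARGETS


@lru_cache(maxsize=None)
def _pair_transform(t1: str, t2: str) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform placing base t2 opposite base t1 (at the template
    origin frame) with near-ideal pair hydrogen-bond distances.

    Solved with the purine as the reference base; the swapped ordering
    is the exact inverse transform, so both views share one geometry.
    """
    if (t1, t2) not in _WC_TARGETS:
        raise StructureError(f"no pairing geometry for {t1}-{t2}")
    if t1 not in chemdata.PURINES and t2 in chemdata.PURINES:
        R, t = _pair_transform(t2, t1)
        return R.T, -(R.T @ t)
    targets = _WC_TARGETS[(t1, t2)]
    tmpl1 = chemdata.base_template(t1)
    names2, coords2, rc2 = _template_arrays(t2)
    idx2 = {n: i for i, n in enumerate(names2)}
    ring2 = [idx2[n] for n in chemdata.ring_atom_names(t2)]
    c1p_1 = tmpl1["C1'"]
    tri2 = [idx2["N1"], idx2["C2"], idx2["N3"]]
    names1 = list(tmpl1)
    coords1 = np.array([tmpl1[n] for n in names1])
    target_pairs = {(a1, a2) for a1, a2, _ in targets}
    don1 = set(chemdata.NUC_BASE_DONORS[t1])
    acc1 = set(chemdata.NUC_BASE_ACCEPTORS[t1])
    don2 = set(chemdata.NUC_BASE_DONORS[t2])
    acc2 = set(chemdata.NUC_BASE_ACCEPTORS[t2])
    # cross-pair distance floors: ordinary sterics at 2.8 A, but
    # non-planted donor-acceptor pairs must stay out of detection range
    floors = np.zeros((len(names1), len(names2)))
    for i, n1_name in enumerate(names1):
        for j, n2_name in enumerate(names2):
            if (n1_name, n2_name) in target_pairs:
                continue
            if ((n1_name in don1 and n2_name in acc2)
                    or (n1_name in acc1 and n2_name in don2)):
                floors[i, j] = 3.6
            else:
                floors[i, j] = 2.8

    def apply(params: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return coords2 @ R.T + params[3:]

    def residuals(params: np.ndarray) -> np.ndarray:
        placed = apply(params)
        res = []
        for a1, a2, d in targets:
            res.append(2.5 * (np.linalg.norm(tmpl1[a1] - placed[idx2[a2]]) - d))
        dmat = np.linalg.norm(coords1[:, None, :] - placed[None, :, :], axis=2)
        res.extend(1.2 * np.maximum(0.0, floors - dmat).ravel())
        ring_z = placed[ring2][:, 2]
        res.extend(3.0 * ring_z)  # coplanarity with base 1
        # cis-glycosidic arrangement: both C1' on the same side of the
        # pair's long axis (this selects the proper pairing branch over
        # sheared look-alikes that satisfy the distance targets)
        cen2 = placed[ring2].mean(axis=0)
        a = cen2 / (np.linalg.norm(cen2) + 1e-12)
        p1 = c1p_1 - np.dot(c1p_1, a) * a
        v2 = placed[idx2["C1'"]] - cen2
        p2 = v2 - np.dot(v2, a) * a
        cos_side = float(np.dot(p1, p2)
                         / (np.linalg.norm(p1) * np.linalg.norm(p2) + 1e-12))
        res.append(3.0 * max(0.0, 0.5 - cos_side))
        # the partner base is flipped: its signed ring normal must be -z
        n1p, c2p, n3p = placed[tri2]
        n2 = np.cross(c2p - n1p, n3p - c2p)
        n2 = n2 / np.linalg.norm(n2)
        res.append(2.0 * (n2[2] + 1.0))
        res.append(0.5 * (np.linalg.norm(c1p_1 - placed[idx2["C1'"]]) - 10.4))
        return np.asarray(res)

    best = None
    for y0 in (8.0, 9.0, 10.0):
        for rotz in (-30.0, 0.0, 30.0):
            R0 = (Rotation.from_euler("z", rotz, degrees=True)
                  * Rotation.from_euler("x", 180, degrees=True))
            x0 = np.concatenate([R0.as_rotvec(), [0.0, y0, 0.0]])
            sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return R, best.x[3:].copy()


def _angle_deg(vertex, p, q) -> float:
    u, v = p - vertex, q - vertex
    return math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)),
                                   float(np.dot(u, v))))


def _place_third(base: str, contacts: list[tuple[str, np.ndarray, float]],
                 guess_centroid: np.ndarray, gly_anchor: np.ndarray,
                 normal: np.ndarray,
                 xi_context: tuple[np.ndarray, np.ndarray, float] | None = None,
                 avoid: np.ndarray | None = None,
                 plane_weight: float = 2.0,
                 reach: float = 8.0) -> dict[str, np.ndarray]:
    """Superpose an ideal base so that the planted donor-acceptor
    contacts are satisfied, optionally steering the ring centroid to a
    target classification-angle value and away from existing atoms."""
    names, coords, rc = _template_arrays(base)
    idx = {n: i for i, n in enumerate(names)}
    init = _place_base_at(base, guess_centroid, gly_anchor, normal)
    init_arr = np.array([init[n] for n in names])
    # recover the initial rigid transform from template to init placement
    R0, _ = _kabsch(coords, init_arr)
    t0 = init_arr.mean(axis=0) - coords.mean(axis=0) @ R0.T
    ring_idx = [idx[n] for n in chemdata.ring_atom_names(base)]
    nrm = np.asarray(normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)

    def apply(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return coords @ R.T + params[3:]

    def residuals(params):
        placed = apply(params)
        res = []
        for aname, point, d in contacts:
            res.append(3.0 * (np.linalg.norm(placed[idx[aname]] - point) - d))
        centroid = placed[ring_idx].mean(axis=0)
        if xi_context is not None:
            vertex, distal, target = xi_context
            res.append((_angle_deg(vertex, centroid, distal) - target) / 4.0)
        # keep the base plane parallel to the host pair plane
        ring = placed[ring_idx] - centroid
        _, _, vt = np.linalg.svd(ring)
        res.append(plane_weight * (1.0 - abs(float(np.dot(vt[2], nrm)))))
        # aim the glycosidic direction back toward the flanking backbone
        gly_dir = placed[idx["C1'"]] - centroid
        to_anchor = gly_anchor - centroid
        cosg = float(np.dot(gly_dir, to_anchor) /
                     (np.linalg.norm(gly_dir) * np.linalg.norm(to_anchor) + 1e-12))
        res.append(2.0 * (1.0 - cosg))
        # soft cap on how far C1' may stray from the flanking backbone
        res.append(1.0 * max(0.0, float(
            np.linalg.norm(placed[idx["C1'"]] - gly_anchor)) - reach))
        if avoid is not None and len(avoid):
            d = np.linalg.norm(placed[:, None, :] - avoid[None, :, :], axis=2)
            res.extend(1.5 * np.maximum(0.0, 2.7 - d.min(axis=1)))
        return np.asarray(res)

    x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    placed = apply(sol.x)
    return dict(zip(names, placed))


def _kabsch(P, Q):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


# ---------------------------------------------------------------------------
# backbone threading
# ---------------------------------------------------------------------------

_SEGMENT_BONDS = [1.52, 1.42, 1.60, 1.59, 1.44, 1.51]
_SEGMENT_NAMES = ["C3'", "O3'", "P", "O5'", "C5'"]  # between C4'(k-1) and C4'(k)


def _arc_points(a: np.ndarray, b: np.ndarray, bow: np.ndarray,
                lengths: Sequence[float]) -> np.ndarray:
    """Interior points of a circular-arc chain from a to b whose
    consecutive arc lengths are ``lengths`` (bonds come out within a
    couple of percent of the targets)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    total = float(np.sum(lengths))
    chord = float(np.linalg.norm(b - a))
    if chord >= total * 0.999:
        # straight line; bonds uniformly scaled
        fracs = np.cumsum(lengths)[:-1] / total
        return a + np.outer(fracs, b - a)
    # solve chord = total * sinc(theta/2)
    lo, hi = 1e-9, 2.0 * math.pi - 1e-6

    def sinc_half(theta):
        return math.sin(theta / 2.0) / (theta / 2.0)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if sinc_half(mid) > chord / total:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    radius = total / theta
    ab = b - a
    w = np.asarray(bow, float)
    w = w - np.dot(w, ab) / np.dot(ab, ab) * ab
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        w = np.cross(ab, [0.0, 0.0, 1.0])
        nw = np.linalg.norm(w)
        if nw < 1e-8:
            w = np.cross(ab, [1.0, 0.0, 0.0])
            nw = np.linalg.norm(w)
    w = w / nw
    mid_ab = 0.5 * (a + b)
    center = mid_ab - radius * math.cos(theta / 2.0) * w
    axis = np.cross(w, ab)
    axis = axis / np.linalg.norm(axis)
    vel = np.cross(axis, a - center)
    if np.dot(vel, w) < 0:
        axis = -axis
    fracs = np.cumsum(lengths)[:-1] / total
    pts = []
    for f in fracs:
        rot = Rotation.from_rotvec(axis * (theta * f)).as_matrix()
        pts.append(center + rot @ (a - center))
    return np.array(pts)


def _phosphate_oxygens(p: np.ndarray, prev_pt: np.ndarray, next_pt: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    t = next_pt - prev_pt
    t = t / np.linalg.norm(t)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(t, ref)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return p + 1.48 * e1, p + 1.48 * (-0.33 * e1 + 0.94 * e2)


# ---------------------------------------------------------------------------
# hairpin builder
# ---------------------------------------------------------------------------

def _normalize_sequence(sequence) -> dict[int, str]:
    if sequence is None:
        return dict(_WT)
    if isinstance(sequence, str):
        if len(sequence) != 34:
            raise ValueError("sequence must cover nucleotides 37-70 (34 nt)")
        return {37 + i: b for i, b in enumerate(sequence.upper())}
    return {int(k): str(v).upper() for k, v in dict(sequence).items()}


def build_hairpin(sequence=None, template: str | FamilyTemplate = "M2",
                  seed: int = 0) -> tuple[Conformation, PlantedTruth]:
    """Build one hairpin conformation realizing a family template.

    Same (sequence, template, seed) gives bit-identical coordinates.
    """
    seq = _normalize_sequence(sequence)
    if isinstance(template, str):
        try:
            template = TEMPLATES[template.upper()]
        except KeyError:
            raise ValueError(f"unknown template {template!r}") from None
    for n in range(37, 71):
        if n not in seq or seq[n] not in chemdata.RNA_BASES:
            raise ValueError(f"sequence must define nucleotide {n}")
    for i, j in PAIR_SCHEME:
        if not wc_compatible(seq[i], seq[j]):
            raise StructureError(
                f"sequence incompatible with pairing scheme: {seq[i]}{i}-{seq[j]}{j}")

    rng = np.random.default_rng(seed)
    xi_target = template.target_xi + rng.uniform(-4.0, 4.0)

    # --- paired stack ---------------------------------------------------
    base_atoms: dict[int, dict[str, np.ndarray]] = {}
    for level, (n1, n2) in enumerate(PAIR_SCHEME):
        t1, t2 = seq[n1], seq[n2]
        tmpl1 = chemdata.base_template(t1)
        names2, coords2, _ = _template_arrays(t2)
        Rp, tp = _pair_transform(t1, t2)
        Rg = Rotation.from_euler("z", TWIST_DEG * level, degrees=True).as_matrix()
        disp = np.array([X_DISPLACEMENT, 0.0, 0.0])
        tg = np.array([0.0, 0.0, RISE * level])
        base_atoms[n1] = {n: Rg @ (p + disp) + tg for n, p in tmpl1.items()}
        placed2 = coords2 @ Rp.T + tp + disp
        base_atoms[n2] = {n: Rg @ p + tg for n, p in zip(names2, placed2)}

    def centroid(num: int) -> np.ndarray:
        ring = chemdata.ring_atom_names(seq[num])
        return np.array([base_atoms[num][n] for n in ring]).mean(axis=0)

    ez = np.array([0.0, 0.0, 1.0])
    vertex = 0.5 * (centroid(43) + centroid(66))
    distal = 0.5 * (centroid(45) + centroid(64))

    def gly_anchor(na: int, nb: int) -> np.ndarray:
        return 0.5 * (base_atoms[na]["C1'"] + base_atoms[nb]["C1'"])

    def radial(num_a: int, num_b: int) -> np.ndarray:
        m = gly_anchor(num_a, num_b)
        u = np.array([m[0], m[1], 0.0])
        return u / np.linalg.norm(u)

    stack_coords = np.array([p for num in base_atoms
                             for p in base_atoms[num].values()])

    def extrude(num: int, na: int, nb: int, radius: float, z: float,
                azimuth_deg: float = 0.0) -> None:
        u = radial(na, nb)
        if azimuth_deg:
            u = Rotation.from_euler("z", azimuth_deg, degrees=True).as_matrix() @ u
        cen = u * radius + np.array([0.0, 0.0, z])
        base_atoms[num] = _place_base_at(seq[num], cen, gly_anchor(na, nb), ez)

    # --- bulged uridines per template ------------------------------------
    def hoogsteen_contacts(third: int, purine: int) -> list:
        # U(N3-H)...N7 and U(O4)...H-N6 of the pair's purine
        return [("N3", base_atoms[purine]["N7"], 2.80),
                ("O4", base_atoms[purine]["N6"], 2.80)]

    def _swing_u63_out() -> None:
        # swung out of the groove: past A65 as seen from its pair
        # partner U44 (large U44-A65-U63 angle), biased away from the
        # major-groove mouth so the swing actually opens the groove
        out = _unit(centroid(65) - centroid(44))
        theta_mid = math.radians(TWIST_DEG * 4.5)
        groove_dir = np.array([math.cos(theta_mid), math.sin(theta_mid), 0.0])
        best = None
        for ang in (0.0, 50.0, -50.0):
            d = Rotation.from_euler("z", ang, degrees=True).as_matrix() @ out
            cen = centroid(65) + 4.5 * d + 2.5 * ez
            u44_dir = centroid(44) - centroid(65)
            opening = math.degrees(math.atan2(
                np.linalg.norm(np.cross(u44_dir, cen - centroid(65))),
                float(np.dot(u44_dir, cen - centroid(65)))))
            away = -float(np.dot(_unit(np.array([cen[0], cen[1], 0.0])),
                                 groove_dir))
            if opening >= 110.0 and (best is None or away > best[0]):
                best = (away, cen)
        cen = best[1] if best else centroid(65) + 4.5 * out + 2.5 * ez
        base_atoms[63] = _place_base_at(seq[63], cen, gly_anchor(62, 64), ez)

    z2 = RISE * 2
    if template.name == "M1":
        # T1: U40 joins C45-G64 (contacts to G64 Hoogsteen edge and C45 N4)
        g64 = base_atoms[64]
        guess = g64["N7"] + 3.0 * _unit(g64["N7"] - centroid(64)) \
            - np.array([0.0, 0.0, 2.5])
        # the third base may tilt out of the pair plane: the compact M1
        # fold bridges the pair from below so its sugar stays reachable
        base_atoms[40] = _place_third(
            seq[40],
            [("N3", g64["N7"], 2.80), ("O4", base_atoms[45]["N4"], 2.80)],
            guess, gly_anchor(39, 42), ez,
            xi_context=(vertex, distal, xi_target), avoid=stack_coords,
            plane_weight=0.3, reach=6.5)
        # T3: U41 on the Hoogsteen edge of A43
        a43 = base_atoms[43]
        guess = a43["N7"] + 3.8 * _unit(a43["N7"] - centroid(43))
        base_atoms[41] = _place_third(
            seq[41], hoogsteen_contacts(41, 43), guess,
            gly_anchor(39, 42), ez, avoid=stack_coords)
        # U63 buried: stacked under the U44-A65 pair (far enough below
        # the pair plane that no in-plane hydrogen bonds appear)
        mid44 = 0.5 * (centroid(44) + centroid(65))
        base_atoms[63] = _place_base_at(
            seq[63], mid44 - 3.9 * ez, gly_anchor(62, 64), ez)
    elif template.name in ("M2", "M2STAR"):
        a43 = base_atoms[43]
        guess = a43["N7"] + 3.8 * _unit(a43["N7"] - centroid(43))
        base_atoms[40] = _place_third(
            seq[40], hoogsteen_contacts(40, 43), guess,
            gly_anchor(39, 42), ez,
            xi_context=(vertex, distal, xi_target), avoid=stack_coords)
        extrude(41, 39, 42, 6.5, z2 + 2.0, azimuth_deg=30.0)
        if template.name == "M2STAR":
            a65 = base_atoms[65]
            guess = a65["N7"] + 3.8 * _unit(a65["N7"] - centroid(65))
            base_atoms[63] = _place_third(
                seq[63], [("N3", a65["N7"], 2.80), ("O4", a65["N6"], 2.80)],
                guess, gly_anchor(62, 64), ez, avoid=stack_coords,
                plane_weight=0.5, reach=6.0)
        else:
            _swing_u63_out()
    elif template.name == "E":
        extrude(40, 39, 42, 5.0, z2 - 3.0)
        extrude(41, 39, 42, 6.5, z2 + 2.0, azimuth_deg=30.0)
        _swing_u63_out()
    else:
        raise ValueError(f"unknown template {template.name!r}")

    # --- loop 49-59 on an arc above the upper stem ------------------------
    def c4p_from_base(num: int) -> np.ndarray:
        rc = centroid(num)
        c1p = base_atoms[num]["C1'"]
        return c1p + 2.35 * _unit(c1p - rc)

    # paired residues get canonical helical sugar anchors so the strand
    # backbones wind smoothly regardless of base identity; bulges derive
    # their anchor from the placed base
    c4p: dict[int, np.ndarray] = {}
    for level, (n1, n2) in enumerate(PAIR_SCHEME):
        Rg = Rotation.from_euler("z", TWIST_DEG * level, degrees=True).as_matrix()
        tg = np.array([0.0, 0.0, RISE * level])
        c4p[n1] = Rg @ np.array([X_DISPLACEMENT, -5.2, 0.0]) + tg
        c4p[n2] = Rg @ np.array([X_DISPLACEMENT, 9.2, 0.0]) + tg
    max_chord = 0.93 * float(np.sum(_SEGMENT_BONDS))
    for num, (fa, fb) in ((40, (39, 42)), (41, (39, 42)), (63, (62, 64))):
        c1p = base_atoms[num]["C1'"]
        mid = 0.5 * (c4p[fa] + c4p[fb])
        c4p[num] = c1p + 2.35 * _unit(mid - c1p)
    # pull bulge sugar anchors toward their chain neighbours until every
    # connecting segment can be threaded with near-ideal bonds; the
    # C1'-C4' separation is sacrificed first (those two atoms are not
    # covalently bonded in the reduced atom set)
    for _ in range(4):
        for num, (prev_n, next_n) in ((40, (39, 41)), (41, (40, 42)),
                                      (63, (62, 64))):
            mid = 0.5 * (c4p[prev_n] + c4p[next_n])
            ideal = c4p[num]
            lo, hi = 0.0, 1.0
            for _ in range(40):
                t = 0.5 * (lo + hi)
                cand = mid + t * (ideal - mid)
                if max(np.linalg.norm(cand - c4p[prev_n]),
                       np.linalg.norm(cand - c4p[next_n])) <= max_chord:
                    lo = t
                else:
                    hi = t
            c4p[num] = mid + lo * (ideal - mid)
    loop_gaps = [5.9] * (len(LOOP) + 1)
    loop_anchor_pts = _arc_points(c4p[48], c4p[60], ez, loop_gaps)
    loop_center = loop_anchor_pts.mean(axis=0)
    for num, pt in zip(LOOP, loop_anchor_pts):
        c4p[num] = pt
        out = _unit(pt - loop_center)
        cen = pt + 3.5 * out
        normal = _unit(np.cross(ez, out))
        base_atoms[num] = _place_base_at(seq[num], cen, pt, normal)

    # --- thread the backbone ---------------------------------------------
    per_res_atoms: dict[int, dict[str, np.ndarray]] = {
        n: dict(base_atoms[n]) for n in range(37, 71)}
    for n in range(37, 71):
        per_res_atoms[n]["C4'"] = c4p[n]
    for k in range(38, 71):
        a_pt, b_pt = c4p[k - 1], c4p[k]
        mid = 0.5 * (a_pt + b_pt)
        if 49 <= k - 1 <= 59 or 49 <= k <= 59:
            bow = _unit(mid - loop_center) if np.linalg.norm(mid - loop_center) > 1e-6 else ez
        else:
            bow = _unit(np.array([mid[0], mid[1], 0.0])) \
                if np.hypot(mid[0], mid[1]) > 1e-6 else np.array([1.0, 0.0, 0.0])
        interior = _arc_points(a_pt, b_pt, bow, _SEGMENT_BONDS)
        owner = [k - 1, k - 1, k, k, k]
        for name, num, pt in zip(_SEGMENT_NAMES, owner, interior):
            per_res_atoms[num][name] = pt
        op1, op2 = _phosphate_oxygens(interior[2], interior[1], interior[3])
        per_res_atoms[k]["OP1"] = op1
        per_res_atoms[k]["OP2"] = op2
    # 3'-terminal stub
    t = _unit(c4p[70] - c4p[69])
    per_res_atoms[70]["C3'"] = c4p[70] + 1.52 * t
    per_res_atoms[70]["O3'"] = per_res_atoms[70]["C3'"] + 1.42 * t

    # --- assemble, with a whisper of seeded jitter ------------------------
    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'"]
    residues = []
    serial = 0
    for n in range(37, 71):
        atoms = []
        names = [nm for nm in order if nm in per_res_atoms[n]]
        names += [nm for nm in per_res_atoms[n] if nm not in order]
        for nm in names:
            serial += 1
            element = "P" if nm == "P" else nm[0]
            atoms.append(Atom(nm, element, per_res_atoms[n][nm], serial))
        residues.append(Residue("A", n, seq[n], atoms))
    conf = Conformation(residues, tag=f"{template.name}:seed{seed}")
    noise = rng.normal(0.0, 0.02, size=(sum(len(r.atoms) for r in residues), 3))
    conf.set_coords(conf.coords() + noise)
    truth = PlantedTruth("family", {
        "family": template.family, "template": template.name,
        "target_xi": xi_target, "triplets": list(template.triplets),
        "u63_mode": template.u63_mode}, seed)
    return conf, truth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# ensembles and mixtures
# ---------------------------------------------------------------------------

def jitter_ensemble(conf: Conformation, n: int, sigma: float, seed: int = 0
                    ) -> tuple[Ensemble, PlantedTruth]:
    """n copies with isotropic Gaussian atomic noise.

    ``sigma`` is the RMS 3-D displacement per atom (each coordinate gets
    independent noise of standard deviation sigma/sqrt(3)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    xyz = conf.coords()
    frames = []
    comp = sigma / math.sqrt(3.0)
    for i in range(n):
        frame = conf.copy()
        frame.tag = f"{conf.tag}|jit{i}"
        if sigma > 0:
            frame.set_coords(xyz + rng.normal(0.0, comp, size=xyz.shape))
        frames.append(frame)
    truth = PlantedTruth("family", {"n": n, "sigma": sigma, "source": conf.tag},
                         seed)
    return Ensemble(frames), truth


def largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Deterministic rounding of n*fractions to integers summing to n."""
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = fr * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    order = np.lexsort((np.arange(len(fr)), -remainder))
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def make_mixture(templates: Sequence[str | FamilyTemplate],
                 fractions: Sequence[float], n: int, sigma: float = 0.3,
                 seed: int = 0, sequence=None
                 ) -> tuple[Ensemble, PlantedTruth]:
    """Shuffled ensemble with planted per-family counts.

    Counts follow the largest-remainder rule; the truth payload records
    the exact planted counts and the per-frame labels.
    """
    if len(templates) != len(fractions):
        raise ValueError("templates and fractions must align")
    counts = largest_remainder_counts(fractions, n)
    active = sum(1 for f in fractions if f > 0)
    if n < active:
        raise ValueError("n smaller than the number of populated templates")
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    resolved = [TEMPLATES[t.upper()] if isinstance(t, str) else t
                for t in templates]
    for idx, (tpl, count) in enumerate(zip(resolved, counts)):
        if count == 0:
            continue
        sub = int(rng.integers(0, 2**31 - 1))
        conf, _ = build_hairpin(sequence, tpl, seed=sub)
        ens, _ = jitter_ensemble(conf, count, sigma,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        frames.extend(ens.frames)
        labels.extend([tpl.family] * count)
    perm = rng.permutation(len(frames))
    frames = [frames[i] for i in perm]
    labels = [labels[i] for i in perm]
    truth = PlantedTruth("composition", {
        "counts": {t.name: c for t, c in zip(resolved, counts)},
        "family_counts": _family_counts(resolved, counts),
        "labels": labels, "n": n, "sigma": sigma}, seed)
    return Ensemble(frames), truth


def _family_counts(templates: Sequence[FamilyTemplate],
                   counts: Sequence[int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for t, c in zip(templates, counts):
        out[t.family] = out.get(t.family, 0) + c
    return out


# ---------------------------------------------------------------------------
# planted kinetic transition networks
# ---------------------------------------------------------------------------

def planted_network(funnels: Sequence[tuple[int, float, float]],
                    inter_barrier: float = 20.0, seed: int = 0,
                    families: Sequence[str] | None = None
                    ) -> tuple[TransitionNetwork, PlantedTruth]:
    """Random multi-funnel network with known funnel membership.

    Each funnel (n_minima, bottom_energy, depth_scale) is a random tree:
    minima energies are bottom + Exp(depth_scale) increments and each
    intra-funnel transition state sits an Exp(depth_scale) increment
    above the higher of the two minima it connects.  Funnel bottoms are
    chained by single transition states at ``inter_barrier``, which must
    exceed every intra-funnel barrier.
    """
    if not funnels:
        raise ValueError("at least one funnel required")
    rng = np.random.default_rng(seed)
    minima: dict[int, Minimum] = {}
    tss: list[TransitionStateRec] = []
    membership: dict[int, int] = {}
    bottoms: list[int] = []
    next_id = 1
    max_intra = -math.inf
    for f_idx, (n_min, bottom_e, depth) in enumerate(funnels):
        if n_min < 1:
            raise ValueError("each funnel needs at least one minimum")
        fam = families[f_idx] if families else None
        ids = []
        for k in range(n_min):
            e = bottom_e if k == 0 else bottom_e + rng.exponential(depth)
            minima[next_id] = Minimum(next_id, float(e), family=fam)
            membership[next_id] = f_idx
            ids.append(next_id)
            next_id += 1
        bottoms.append(ids[0])
        for k in range(1, n_min):
            other = ids[int(rng.integers(0, k))]
            hi = max(minima[ids[k]].energy, minima[other].energy)
            ts_e = hi + rng.exponential(depth)
            max_intra = max(max_intra, ts_e)
            tss.append(TransitionStateRec(len(tss) + 1, float(ts_e),
                                          ids[k], other))
    for a, b in zip(bottoms, bottoms[1:]):
        if inter_barrier <= max_intra:
            raise ValueError(
                f"inter_barrier {inter_barrier} not above intra barriers "
                f"(max {max_intra:.3f})")
        tss.append(TransitionStateRec(len(tss) + 1, float(inter_barrier), a, b))
    net = TransitionNetwork(minima, tss)
    truth = PlantedTruth("funnel", {
        "membership": {str(k): v for k, v in membership.items()},
        "bottoms": bottoms, "inter_barrier": inter_barrier,
        "families": list(families) if families else None}, seed)
    return net, truth


# ---------------------------------------------------------------------------
# ARM peptide and complex poses
# ---------------------------------------------------------------------------

_SIDE_TIPS = {
    "LYS": [("CG", 2.9), ("CD", 4.2), ("CE", 5.5), ("NZ", 6.4)],
    "ARG": [("CG", 2.9), ("CD", 4.2), ("NE", 5.4), ("CZ", 6.1),
            ("NH1", 7.0), ("NH2", 6.9)],
    "HIS": [("CG", 2.9), ("ND1", 4.0), ("NE2", 4.6)],
    "SER": [("OG", 2.4)],
    "PRO": [("CG", 2.4), ("CD", 1.9)],
    "TRP": [("CG", 2.9), ("NE1", 4.3)],
}
_SIDE_SPREAD = {"NH1": 0.9, "NH2": -0.9, "ND1": 0.7, "NE2": -0.7, "CD": 0.8}


def build_arm_peptide(sequence: str = ARM_SEQUENCE, chain: str = "B",
                      start_number: int = 149) -> Conformation:
    """Compact helical ARM peptide with backbone and pseudo side chains.

    CA atoms follow an alpha-helical rod along +x (rise 1.5 A and 100
    degrees per residue on a 2.3 A radius); side-chain tip atoms lean
    toward the local +z face of the rod, so a single rigid placement
    aims every basic side chain at the RNA while the opposite face
    stays slim.  Residues are numbered from 149, matching the HEXIM1
    149-165 convention.
    """
    residues = []
    serial = 0
    ez = np.array([0.0, 0.0, 1.0])
    for i, one in enumerate(sequence):
        name3 = chemdata.AMINO_ACIDS_1TO3[one.upper()]
        ang = math.radians(100.0 * i)
        rad = np.array([0.0, math.cos(ang), math.sin(ang)])
        ca = np.array([1.5 * i, 0.0, 0.0]) + 1.3 * rad
        ex = np.array([1.0, 0.0, 0.0])
        perp = np.cross(ex, rad)
        side = _unit(0.35 * rad + 0.95 * ez)
        atoms = {
            "CA": ca,
            "N": ca - 1.2 * ex + 0.8 * perp,
            "C": ca + 1.25 * ex + 0.6 * perp,
        }
        atoms["O"] = atoms["C"] + 1.23 * rad
        if name3 != "GLY":
            atoms["CB"] = ca + 1.53 * side
        for tip, dist in _SIDE_TIPS.get(name3, []):
            spread = _SIDE_SPREAD.get(tip, 0.0)
            atoms[tip] = ca + dist * side + spread * perp
        res_atoms = []
        for nm, pos in atoms.items():
            serial += 1
            res_atoms.append(Atom(nm, nm[0], pos, serial))
        residues.append(Residue(chain, start_number + i, name3, res_atoms))
    return Conformation(residues, tag="ARM")


def _helix_frame(rna: Conformation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(center, axis, major-groove direction) of the GAUC/GAUC helix."""
    from .geometry import base_centroid, base_plane_normal
    mids, normals = [], []
    for n1, n2 in [(42, 67), (43, 66), (44, 65), (45, 64)]:
        mids.append(0.5 * (base_centroid(rna.residue(n1))
                           + base_centroid(rna.residue(n2))))
        for n in (n1, n2):
            nm = base_plane_normal(rna.residue(n))
            if normals and np.dot(nm, normals[0]) < 0:
                nm = -nm
            normals.append(nm)
    mids = np.array(mids)
    # base planes are perpendicular to the stack axis; their mean normal
    # is a far more robust axis estimate than a line fit through a few
    # winding pair midpoints
    axis = _unit(np.mean(normals, axis=0))
    if axis[2] < 0:
        axis = -axis
    # the pair midpoints wind around the helix axis; a least-squares
    # circle fit in the plane perpendicular to the axis locates the
    # axis, and the open (major-groove) side is opposite the mean pair
    # displacement
    e1 = _unit(np.cross(axis, [1.0, 0.0, 0.0])
               if abs(axis[0]) < 0.9 else np.cross(axis, [0.0, 1.0, 0.0]))
    e2 = np.cross(axis, e1)
    xy = np.column_stack([mids @ e1, mids @ e2])
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    (cx, cy, _), *_ = np.linalg.lstsq(A, b, rcond=None)
    axis_point = cx * e1 + cy * e2 + np.dot(mids.mean(axis=0), axis) * axis
    disp = mids.mean(axis=0) - axis_point
    disp = disp - np.dot(disp, axis) * axis
    groove = -_unit(disp)
    return axis_point, axis, groove


def place_peptide(rna: Conformation, mode: str = "groove", seed: int = 0,
                  peptide: Conformation | None = None
                  ) -> tuple[Conformation, PlantedTruth]:
    """Rigidly place the ARM peptide against the hairpin.

    Modes: 'groove' (aligned with the GAUC/GAUC helix axis, starting
    about 6 A from it on the major-groove side), 'surface' (tangential
    at van der Waals contact with the backbone) and 'distant' (50 A
    offset).  The pose is retracted outward in 0.5 A steps until no
    heavy-atom pair is closer than 2.2 A.
    """
    if mode not in ("groove", "surface", "distant"):
        raise ValueError(f"unknown mode {mode!r}")
    pep = (peptide or build_arm_peptide()).copy()
    rng = np.random.default_rng(seed)
    center, axis, groove = _helix_frame(rna)

    motif = {42, 43, 44, 45, 46, 63, 64, 65, 66, 67, 68}
    p_radii = [np.linalg.norm((r.atom("P").position - center)
                              - np.dot(r.atom("P").position - center, axis) * axis)
               for r in rna
               if r.is_nucleotide and r.has_atom("P") and r.number in motif]
    backbone_radius = max(p_radii) if p_radii else 10.0
    t_hat = _unit(np.cross(axis, groove))
    if mode == "groove":
        # the major groove is a helical channel; the rod follows its
        # local tangent, side chains inward, pushed as deep toward the
        # motif as sterics allow
        groove_radius = 8.0
        direction = _unit(RISE * axis
                          + groove_radius * math.radians(TWIST_DEG) * t_hat)
        # slim backbone face inward: the rod body occupies the channel
        # and the CA trace penetrates toward the bases
        radius, u = 4.0, groove
    elif mode == "surface":
        # tangential across the outside of the backbone, side chains
        # pointing away from the RNA
        radius = backbone_radius + 2.0
        direction, u = t_hat, groove
    else:
        radius, direction, u = 50.0, axis, -groove
    radius += rng.uniform(0.0, 0.3)

    pep_xyz = pep.coords()
    pep_center = pep_xyz.mean(axis=0)
    u = _unit(u - np.dot(u, direction) * direction)
    R = np.column_stack([direction, np.cross(u, direction), u])
    rna_xyz = np.vstack([a.position for _, a in rna.atoms()])

    placed = None
    max_extra = 20.0
    extra = 0.0
    from scipy.spatial import cKDTree
    rna_tree = cKDTree(rna_xyz)
    while extra <= max_extra:
        target = center + (radius + extra) * groove
        moved = (pep_xyz - pep_center) @ R.T + target
        dmin = rna_tree.query(moved)[0].min()
        if dmin >= 2.2:
            placed = moved
            break
        extra += 0.25
    if placed is None:
        raise StructureError("cannot satisfy clash rule within 20 A retraction")
    pep.set_coords(placed)
    complex_conf = Conformation([r.copy() for r in rna.residues]
                                + [r.copy() for r in pep.residues],
                                tag=f"{rna.tag}+ARM:{mode}")
    truth = PlantedTruth("pose", {
        "mode": mode, "radius": radius + extra,
        "rna_tag": rna.tag}, seed)
    return complex_conf, truth
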