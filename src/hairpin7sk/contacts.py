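"""Hydrogen bonds, base pairs and the named base triplets.

The hairpin families are distinguished by which bulged uridine joins
which base pair of the GAUC/GAUC helix:

* T1 = U40 . C45-G64 (compact M1, together with T3)
* T2 = U40 . A43-U66 (M2, the binding-competent family)
* T3 = U41 . A43-U66 (M1)
* U63 . U44-A65      (marks the M2* subset of M2)

Criteria are geometric and heavy-atom based: a donor-acceptor pair
within ``d_max`` (default 3.5 A) counts as a hydrogen bond; when an
explicit donor hydrogen is present the D-H...A angle must additionally
exceed ``angle_min`` (default 120 degrees).  Crystal-style inputs
without hydrogens therefore fall back to the distance criterion alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemdata
from .geometry import base_centroid, base_plane_normal
from .structure import Conformation, Ensemble, Residue, StructureError


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5
    angle_min: float = 120.0  # degrees, applied only when donor H present


@dataclass(frozen=True)
class HBond:
    donor_chain: str
    donor_res: int
    donor_atom: str
    acceptor_chain: str
    acceptor_res: int
    acceptor_atom: str
    distance: float
    dha_angle: float | None = None

    @property
    def donor(self) -> tuple[int, str]:
        return (self.donor_res, self.donor_atom)

    @property
    def acceptor(self) -> tuple[int, str]:
        return (self.acceptor_res, self.acceptor_atom)


@dataclass
class BasePair:
    res_a: int
    res_b: int
    hbonds: list[HBond]
    wc_flag: bool

    def members(self) -> tuple[int, int]:
        return (self.res_a, self.res_b)


#: canonical triplet member sets: label -> (third base, pair)
CANONICAL_TRIPLETS = {
    "T1": (40, (45, 64)),
    "T2": (40, (43, 66)),
    "T3": (41, (43, 66)),
    "M2STAR": (63, (44, 65)),
}


@dataclass
class TripletAnnotation:
    label: str  # T1 / T2 / T3 / M2STAR / OTHER
    members: tuple[int, int, int]  # (third, pair_a, pair_b)
    present: bool
    support: int  # H-bond count from the third base to the pair


# donor hydrogens are named after their heavy atom (H3 on N3, H41/H42 on N4...)
def _donor_hydrogens(res: Residue, donor_name: str) -> list[np.ndarray]:
    suffix = donor_name[1:] if len(donor_name) > 1 else donor_name
    out = []
    for a in res.atoms:
        if a.element == "H" and a.name.startswith("H") and suffix and suffix in a.name:
            if np.linalg.norm(a.position - res.atom(donor_name).position) < 1.3:
                out.append(a.position)
    return out


def detect_hbonds(conf: Conformation,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All inter-residue donor-acceptor contacts satisfying the criteria."""
    donors: list[tuple[Residue, str, np.ndarray]] = []
    acceptors: list[tuple[Residue, str, np.ndarray]] = []
    for res in conf:
        for name in chemdata.donor_atoms(res.name):
            if res.has_atom(name):
                donors.append((res, name, res.atom(name).position))
        for name in chemdata.acceptor_atoms(res.name):
            if res.has_atom(name):
                acceptors.append((res, name, res.atom(name).position))
    if not donors or not acceptors:
        return []
    acc_tree = cKDTree(np.array([p for _, _, p in acceptors]))
    bonds: list[HBond] = []
    for dres, dname, dpos in donors:
        for j in acc_tree.query_ball_point(dpos, criteria.d_max):
            ares, aname, apos = acceptors[j]
            if ares is dres:
                continue
            dist = float(np.linalg.norm(apos - dpos))
            if dist < 1e-6:
                continue
            angle = None
            hydrogens = _donor_hydrogens(dres, dname)
            if hydrogens:
                best = -1.0
                for h in hydrogens:
                    u = dpos - h
                    v = apos - h
                    cosang = float(np.dot(u, v) /
                                   (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12))
                    best = max(best, math.degrees(math.acos(np.clip(cosang, -1, 1))))
                angle = best
                if angle < criteria.angle_min:
                    continue
            bonds.append(HBond(dres.chain, dres.number, dname,
                               ares.chain, ares.number, aname, dist, angle))
    bonds.sort(key=lambda b: (b.donor_chain, b.donor_res, b.donor_atom,
                              b.acceptor_chain, b.acceptor_res, b.acceptor_atom))
    return bonds


def hbond_count(target: Conformation | Ensemble, residue_number: int,
                criteria: HBondCriteria = HBondCriteria()) -> float:
    """Number of H-bonds a residue participates in (mean over frames)."""
    if isinstance(target, Ensemble):
        return float(np.mean([hbond_count(f, residue_number, criteria)
                              for f in target]))
    conf = target
    conf.residue(residue_number)  # raises for unknown residue
    n = 0
    for b in detect_hbonds(conf, criteria):
        if residue_number in (b.donor_res, b.acceptor_res):
            n += 1
    return float(n)


def _base_atom_set(res: Residue) -> set[str]:
    return set(chemdata.base_atom_names(res.name))


def _inter_base_hbonds(bonds: Iterable[HBond], ra: Residue, rb: Residue
                       ) -> list[HBond]:
    base_a, base_b = _base_atom_set(ra), _base_atom_set(rb)
    out = []
    for b in bonds:
        if (b.donor_res == ra.number and b.acceptor_res == rb.number
                and b.donor_atom in base_a and b.acceptor_atom in base_b):
            out.append(b)
        elif (b.donor_res == rb.number and b.acceptor_res == ra.number
                and b.donor_atom in base_b and b.acceptor_atom in base_a):
            out.append(b)
    return out


def detect_base_pairs(conf: Conformation,
                      criteria: HBondCriteria = HBondCriteria(),
                      max_centroid_dist: float = 7.0,
                      max_plane_angle: float = 35.0,
                      max_vertical_offset: float = 2.0) -> list[BasePair]:
    """Base pairs: >= 2 inter-base H-bonds, close centroids, near-coplanar.

    ``max_vertical_offset`` (A) bounds the centroid separation along the
    mean base normal; it rejects stacked neighbours, which in
    hydrogen-free inputs can otherwise satisfy the distance criterion.
    """
    nts = [r for r in conf if r.is_nucleotide]
    if len(nts) < 2:
        return []
    bonds = detect_hbonds(conf, criteria)
    cents, normals = {}, {}
    for r in nts:
        try:
            cents[r.number] = base_centroid(r)
            normals[r.number] = base_plane_normal(r)
        except StructureError:
            continue
    nums = sorted(cents)
    tree = cKDTree(np.array([cents[n] for n in nums]))
    pairs: list[BasePair] = []
    for i, j in sorted(tree.query_pairs(max_centroid_dist)):
        na, nb = nums[i], nums[j]
        ra, rb = conf.residue(na), conf.residue(nb)
        support = _inter_base_hbonds(bonds, ra, rb)
        if len(support) < 2:
            continue
        cosang = abs(float(np.dot(normals[na], normals[nb])))
        plane_angle = math.degrees(math.acos(np.clip(cosang, 0.0, 1.0)))
        if plane_angle > max_plane_angle:
            continue
        mean_normal = normals[na] + np.sign(np.dot(normals[na], normals[nb])) * normals[nb]
        mean_normal = mean_normal / (np.linalg.norm(mean_normal) + 1e-12)
        if abs(float(np.dot(cents[nb] - cents[na], mean_normal))) > max_vertical_offset:
            continue
        wc_a = set(chemdata.WC_EDGE_ATOMS[ra.name])
        wc_b = set(chemdata.WC_EDGE_ATOMS[rb.name])
        wc = all(
            (b.donor_atom in wc_a and b.acceptor_atom in wc_b)
            if b.donor_res == na else
            (b.donor_atom in wc_b and b.acceptor_atom in wc_a)
            for b in support)
        pairs.append(BasePair(min(na, nb), max(na, nb), support, wc))
    return pairs


def detect_triplets(conf: Conformation, min_support: int = 2,
                    criteria: HBondCriteria = HBondCriteria(),
                    pairs: list[BasePair] | None = None) -> list[TripletAnnotation]:
    """Annotate the canonical triplets T1/T2/T3/M2* plus any OTHER joiners.

    A triplet is present when its base pair is detected and the third
    base forms at least ``min_support`` base-base hydrogen bonds with the
    pair members in total.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if pairs is None:
        pairs = detect_base_pairs(conf, criteria)
    pair_index = {p.members(): p for p in pairs}
    bonds = detect_hbonds(conf, criteria)

    def support_count(third: int, pair: tuple[int, int]) -> int:
        if not conf.has_residue(third):
            return 0
        rt = conf.residue(third)
        if not rt.is_nucleotide:
            return 0
        n = 0
        for member in pair:
            n += len(_inter_base_hbonds(bonds, rt, conf.residue(member)))
        return n

    out: list[TripletAnnotation] = []
    canonical_thirds: dict[tuple[int, int], set[int]] = {}
    for label, (third, pair) in CANONICAL_TRIPLETS.items():
        key = (min(pair), max(pair))
        canonical_thirds.setdefault(key, set()).add(third)
        pair_found = key in pair_index
        support = support_count(third, key) if pair_found else 0
        present = pair_found and support >= min_support
        out.append(TripletAnnotation(label, (third, *key), present, support))

    # non-canonical bases joining any detected pair at the same support level
    for key, pair in pair_index.items():
        for r in conf:
            if not r.is_nucleotide or r.number in key:
                continue
            if r.number in canonical_thirds.get(key, set()):
                continue
            support = support_count(r.number, key)
            if support >= min_support:
                out.append(TripletAnnotation("OTHER", (r.number, *key), True, support))
    return out


def triplet_presence(triplets: Sequence[TripletAnnotation]) -> dict[str, bool]:
    """Presence flags for the four canonical triplet labels."""
    flags = {k: False for k in CANONICAL_TRIPLETS}
    for t in triplets:
        if t.label in flags and t.present:
            flags[t.label] = True
    return flags


def _resolve_group(conf: Conformation, sel) -> set[tuple[str, int]]:
    """A group selection: chain id, iterable of residue numbers, or predicate."""
    if isinstance(sel, str):
        return {(r.chain, r.number) for r in conf.chain_residues(sel)}
    if callable(sel):
        return {(r.chain, r.number) for r in conf if sel(r)}
    keys = set()
    numbers = set(sel)
    for r in conf:
        if r.number in numbers:
            keys.add((r.chain, r.number))
    return keys


def hbond_persistence(ens: Ensemble, group_a, group_b,
                      criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Fraction of frames in which each cross-group H-bond is observed.

    Groups may be chain ids, residue-number iterables or predicates; they
    must not overlap.  Returns a DataFrame with one row per observed
    (donor atom, acceptor atom) pair and a ``fraction`` column in (0, 1].
    """
    first = ens.frames[0]
    keys_a = _resolve_group(first, group_a)
    keys_b = _resolve_group(first, group_b)
    if keys_a & keys_b:
        raise ValueError("groups overlap")
    counts: dict[tuple, int] = {}
    for frame in ens:
        for b in detect_hbonds(frame, criteria):
            dk = (b.donor_chain, b.donor_res)
            ak = (b.acceptor_chain, b.acceptor_res)
            if (dk in keys_a and ak in keys_b) or (dk in keys_b and ak in keys_a):
                key = (b.donor_chain, b.donor_res, b.donor_atom,
                       b.acceptor_chain, b.acceptor_res, b.acceptor_atom)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"donor_chain": k[0], "donor_res": k[1], "donor_atom": k[2],
         "acceptor_chain": k[3], "acceptor_res": k[4], "acceptor_atom": k[5],
         "fraction": n / len(ens)}
        for k, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["donor_chain", "donor_res", "donor_atom",
                                       "acceptor_chain", "acceptor_res",
                                       "acceptor_atom", "fraction"])
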