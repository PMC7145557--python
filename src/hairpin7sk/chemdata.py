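"""Bundled chemical reference data.

Idealized planar base geometries, hydrogen-bond donor/acceptor tables,
van der Waals radii, atomic masses and a nominal partial-charge set for
the nucleotides A/C/G/U and the amino acids of the arginine-rich motif.

The base templates are constructed from regular-polygon ring geometry
(hexagon side 1.39 A, fused pentagon side 1.37 A) with exocyclic
substituents placed radially.  They are intended for base-moiety
rebuilding during mutations and for the synthetic fixture builder; they
are geometrically plausible, not force-field optimized.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING = PYRIMIDINE_RING + ("N7", "C8", "N9")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
RNA_BASES = PURINES | PYRIMIDINES

#: glycosidic (sugar-attached) ring nitrogen per base
GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: in-plane reference neighbour of the glycosidic atom, used to build an
#: unambiguous right-handed attachment frame (see structure_io mutations)
FRAME_REFERENCE_ATOM = {"A": "C8", "G": "C8", "C": "C2", "U": "C2"}

_EXOCYCLIC = {"A": ("N6",), "G": ("O6", "N2"), "C": ("O2", "N4"),
              "U": ("O2", "O4")}


@lru_cache(maxsize=None)
def base_template(base: str) -> dict[str, np.ndarray]:
    """Ideal base heavy atoms (plus C1'), canonically oriented.

    Coordinates come from the Chemical Component Dictionary ideal
    geometry bundled with biotite, restricted to the base moiety and
    C1', then re-framed so that the ring plane is z=0, the ring
    centroid sits at the origin and the centroid->C1' direction points
    along -y.  The frame convention makes the glycosidic attachment
    interchangeable between purines and pyrimidines, which is what the
    mutation operator and the helix builder rely on.
    """
    if base not in RNA_BASES:
        raise ValueError(f"unknown base {base!r}")
    import biotite.structure.info as bsinfo

    res = bsinfo.residue(base)
    wanted = list(ring_atom_names(base)) + list(_EXOCYCLIC[base]) + ["C1'"]
    atoms: dict[str, np.ndarray] = {}
    for name in wanted:
        hit = np.where(res.atom_name == name)[0]
        if len(hit) != 1:
            raise ValueError(f"CCD template for {base} lacks atom {name}")
        atoms[name] = np.array(res.coord[hit[0]], dtype=float)

    ring = ring_atom_names(base)
    pts = np.array([atoms[n] for n in ring])
    rc = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - rc)
    normal = vt[2]
    # handedness convention: the N1 -> C2 -> N3 traversal runs
    # counter-clockwise (seen from +z) for pyrimidines and clockwise for
    # purines; this puts the same molecular face up for both, so that a
    # 180-degree flip of the partner produces a proper Watson-Crick
    # arrangement with C1'-C1' near 10.4 A
    n1, c2, n3 = atoms["N1"], atoms["C2"], atoms["N3"]
    sense = np.dot(np.cross(c2 - n1, n3 - c2), normal)
    if (sense < 0) != (base in PURINES):
        normal = -normal
    z = normal
    v = atoms["C1'"] - rc
    y = -(v - np.dot(v, z) * z)
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    frame = np.column_stack([x, y, z])
    return {k: frame.T @ (p - rc) for k, p in atoms.items()}


def ring_atom_names(base: str) -> tuple[str, ...]:
    return PURINE_RING if base in PURINES else PYRIMIDINE_RING


def base_atom_names(base: str) -> tuple[str, ...]:
    """All base-moiety heavy atoms (ring + exocyclic), excluding C1'."""
    return tuple(n for n in base_template(base) if n != "C1'")


# ---------------------------------------------------------------------------
# hydrogen-bond donor / acceptor tables (heavy atoms)
# ---------------------------------------------------------------------------

#: base-moiety donors and acceptors per nucleotide
NUC_BASE_DONORS = {
    "A": ("N6",),
    "C": ("N4",),
    "G": ("N1", "N2"),
    "U": ("N3",),
}
NUC_BASE_ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "C": ("O2", "N3"),
    "G": ("O6", "N3", "N7"),
    "U": ("O2", "O4"),
}
#: backbone/sugar acceptors common to every nucleotide
NUC_BACKBONE_ACCEPTORS = ("OP1", "OP2", "O5'", "O3'", "O2'", "O4'")
#: sugar hydroxyl donor
NUC_BACKBONE_DONORS = ("O2'",)

#: Watson-Crick edge atoms (used to flag canonical pair geometry)
WC_EDGE_ATOMS = {
    "A": ("N1", "N6"),
    "C": ("N3", "N4", "O2"),
    "G": ("N1", "N2", "O6"),
    "U": ("N3", "O2", "O4"),
}

AMINO_ACIDS_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS_1TO3 = {v: k for k, v in AMINO_ACIDS_3TO1.items()}

#: side-chain donors per amino acid (3-letter); backbone N handled separately
AA_SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "CYS": ("SG",),
}
AA_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def donor_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy-atom H-bond donor names for a residue type."""
    if res_name in RNA_BASES:
        return NUC_BASE_DONORS[res_name] + NUC_BACKBONE_DONORS
    if res_name in AMINO_ACIDS_3TO1:
        side = AA_SIDECHAIN_DONORS.get(res_name, ())
        backbone = () if res_name == "PRO" else ("N",)
        return backbone + side
    return ()


def acceptor_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy-atom H-bond acceptor names for a residue type."""
    if res_name in RNA_BASES:
        return NUC_BASE_ACCEPTORS[res_name] + NUC_BACKBONE_ACCEPTORS
    if res_name in AMINO_ACIDS_3TO1:
        return ("O",) + AA_SIDECHAIN_ACCEPTORS.get(res_name, ())
    return ()


# ---------------------------------------------------------------------------
# radii, masses, charges
# ---------------------------------------------------------------------------

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
}

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}

#: formal residue charges at pH 7 (RNA: one phosphate per residue)
FORMAL_CHARGE = {
    **{b: -1.0 for b in RNA_BASES},
    "ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0,
}

#: nominal per-atom partial charges; per-residue totals are corrected to
#: the formal charge at assignment time (see interface.assign_charges)
NOMINAL_CHARGES = {
    "P": 1.20, "OP1": -0.80, "OP2": -0.80, "O5'": -0.50, "O3'": -0.50,
    "C5'": 0.05, "C4'": 0.10, "C3'": 0.10, "C2'": 0.10, "C1'": 0.10,
    "O2'": -0.60, "O4'": -0.40,
    # generic base-atom polarities
    "O2": -0.45, "O4": -0.45, "O6": -0.45,
    "N1": -0.30, "N2": 0.20, "N3": -0.30, "N4": 0.20, "N6": 0.20,
    "N7": -0.30, "N9": 0.05, "C2": 0.30, "C4": 0.30, "C5": 0.0,
    "C6": 0.30, "C8": 0.20,
    # peptide backbone
    "N": -0.40, "CA": 0.10, "C": 0.55, "O": -0.55, "CB": 0.0,
    # charged / polar side-chain tips
    "NZ": 0.80, "NE": 0.30, "CZ": 0.40, "NH1": 0.45, "NH2": 0.45,
    "ND1": -0.20, "NE2": -0.20, "OG": -0.40, "NE1": -0.20,
    "CG": 0.0, "CD": 0.0, "CE": 0.0,
}
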