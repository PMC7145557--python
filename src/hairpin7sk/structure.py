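"""Core in-memory containers: Atom, Residue, Conformation, Ensemble.

Author residue numbering (37-70 for the hairpin window) is the canonical
coordinate system throughout the package; nothing is ever renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from . import chemdata


class StructureError(ValueError):
    """Raised for inconsistent or incomplete structural data."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.serial)


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name}{self.number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_nucleotide(self) -> bool:
        return self.name in chemdata.RNA_BASES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in chemdata.AMINO_ACIDS_3TO1

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.position for a in self.atoms])
        return np.array([self.atom(n).position for n in names])

    def copy(self) -> "Residue":
        return Residue(self.chain, self.number, self.name,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class Conformation:
    residues: list[Residue]
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError("conformation must contain at least one residue")
        seen = set()
        for r in self.residues:
            key = (r.chain, r.number, r.icode)
            if key in seen:
                raise StructureError(f"duplicate residue {key}")
            seen.add(key)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def chain_residues(self, chain: str) -> list[Residue]:
        res = [r for r in self.residues if r.chain == chain]
        if not res:
            raise StructureError(f"no residues on chain {chain!r}")
        return res

    def residue(self, number: int, chain: str | None = None) -> Residue:
        hits = [r for r in self.residues
                if r.number == number and (chain is None or r.chain == chain)]
        if not hits:
            where = f" on chain {chain!r}" if chain else ""
            raise StructureError(f"no residue numbered {number}{where}")
        return hits[0]

    def has_residue(self, number: int, chain: str | None = None) -> bool:
        return any(r.number == number and (chain is None or r.chain == chain)
                   for r in self.residues)

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def coords(self) -> np.ndarray:
        return np.array([a.position for _, a in self.atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        atoms = [a for _, a in self.atoms()]
        if xyz.shape != (len(atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        for a, p in zip(atoms, xyz):
            a.position = p.copy()

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, a in out.atoms():
            a.position = R @ a.position + t
        return out

    def topology_key(self) -> tuple:
        return tuple((r.chain, r.number, r.name) for r in self.residues)

    def copy(self) -> "Conformation":
        return Conformation([r.copy() for r in self.residues], self.tag)


@dataclass
class Ensemble:
    frames: list[Conformation]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("ensemble must contain at least one frame")
        key = self.frames[0].topology_key()
        for i, f in enumerate(self.frames):
            if f.topology_key() != key:
                raise StructureError(f"frame {i} has a different residue topology")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.frames),) or np.any(w < 0):
                raise StructureError("weights must be non-negative, one per frame")
            if abs(w.sum() - 1.0) > 1e-9:
                raise StructureError("weights must sum to 1")
            self.weights = w

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Conformation:
        return self.frames[i]


def validate_nucleotide(res: Residue) -> None:
    """Check that an RNA residue carries the full base ring for its identity."""
    names = chemdata.ring_atom_names(res.name)
    missing = [n for n in names if not res.has_atom(n)]
    if missing:
        raise StructureError(
            f"residue {res.name}{res.number}: missing ring atoms {missing}")


Selection = Callable[[Residue, Atom], bool]


def heavy_atoms(res: Residue, atom: Atom) -> bool:
    return atom.element != "H"


def select_atoms(conf: Conformation, selection: Selection | None = None
                 ) -> list[tuple[Residue, Atom]]:
    sel = selection or heavy_atoms
    return [(r, a) for r, a in conf.atoms() if sel(r, a)]
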