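"""PDB reading/writing, hairpin-window truncation and sequence mutations.

PDB parsing and serialization are delegated to biotite; this module
converts between biotite's AtomArray representation and the package's
residue-centric containers, and implements the mutation operator used to
derive the mutant hairpins (U40C, delU63, A39G+U68C, ...) from a
wild-type model.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb

from . import chemdata
from .structure import Atom, Conformation, Ensemble, Residue, StructureError


class PDBParseError(ValueError):
    """Malformed PDB content, reporting the offending line."""


_SOLVENT_NAMES = {"HOH", "WAT", "DOD", "SOL"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "SR", "CS", "BR", "IOD"}

# map common PDB nucleotide aliases onto single-letter names
_NUC_ALIASES = {"RA": "A", "RC": "C", "RG": "G", "RU": "U",
                "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U"}


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed ATOM record: {line.rstrip()!r}"
                ) from None


def _canonical_res_name(name: str) -> str:
    name = name.strip()
    return _NUC_ALIASES.get(name, name)


def _array_to_conformation(arr: bst.AtomArray, tag: str) -> Conformation:
    residues: list[Residue] = []
    current: tuple | None = None
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.ins_code[i])
        if key != current:
            residues.append(Residue(
                chain=str(arr.chain_id[i]),
                number=int(arr.res_id[i]),
                name=_canonical_res_name(str(arr.res_name[i])),
                icode=str(arr.ins_code[i]).strip(),
            ))
            current = key
        element = str(arr.element[i]).capitalize() or str(arr.atom_name[i])[0]
        residues[-1].atoms.append(Atom(
            name=str(arr.atom_name[i]),
            element=element,
            position=np.array(arr.coord[i], dtype=float),
            serial=i + 1,
        ))
    return Conformation(residues, tag=tag)


def read_pdb(source, models: Sequence[int] | None = None,
             keep_solvent: bool = False) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an Ensemble.

    Parameters
    ----------
    source
        Path, path-like or text stream with PDB content.
    models
        1-based MODEL numbers to keep; ``None`` selects all models.
    keep_solvent
        Keep water and monoatomic ions (dropped by default).

    Alternate locations are resolved to the highest-occupancy copy
    (ties broken by altloc letter order, biotite's convention).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    _validate_pdb_text(text)
    pdb_file = bpdb.PDBFile.read(_io.StringIO(text))
    n_models = pdb_file.get_model_count()
    if models is None:
        selected = list(range(1, n_models + 1))
    else:
        selected = [int(m) for m in models]
        bad = [m for m in selected if m < 1 or m > n_models]
        if bad:
            raise ValueError(f"model selection {bad} outside 1..{n_models}")
    if not selected:
        raise ValueError("empty model selection")

    frames = []
    for m in selected:
        arr = pdb_file.get_structure(model=m, altloc="occupancy",
                                     extra_fields=["occupancy"])
        if not keep_solvent:
            resn = np.char.strip(arr.res_name.astype(str))
            mask = ~(np.isin(resn, sorted(_SOLVENT_NAMES))
                     | np.isin(resn, sorted(_ION_NAMES)))
            arr = arr[mask]
        if arr.array_length() == 0:
            raise StructureError(f"model {m} contains no atoms after filtering")
        tag = f"model{m}" if n_models > 1 else "model1"
        frames.append(_array_to_conformation(arr, tag))
    return Ensemble(frames)


def _conformation_to_array(conf: Conformation) -> bst.AtomArray:
    n = sum(len(r.atoms) for r in conf.residues)
    arr = bst.AtomArray(n)
    i = 0
    for r in conf.residues:
        hetero = not (r.is_nucleotide or r.is_amino_acid)
        for a in r.atoms:
            arr.chain_id[i] = r.chain
            arr.res_id[i] = r.number
            arr.ins_code[i] = r.icode
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.hetero[i] = hetero
            arr.coord[i] = a.position
            i += 1
    return arr


def write_pdb(ens: Ensemble | Conformation, sink, multi_model: bool | None = None) -> None:
    """Write an ensemble as PDB text.

    A single frame is written without MODEL records unless
    ``multi_model=True``; multiple frames always use MODEL/ENDMDL.
    Coordinates are fixed-width with 3 decimals, so round-tripping is
    exact to 0.001 A.
    """
    if isinstance(ens, Conformation):
        ens = Ensemble([ens])
    if not ens.frames:
        raise StructureError("cannot write an empty ensemble")
    arrays = [_conformation_to_array(f) for f in ens.frames]
    pdb_file = bpdb.PDBFile()
    if len(arrays) == 1 and not multi_model:
        pdb_file.set_structure(arrays[0])
    elif len(arrays) == 1:
        pdb_file.set_structure(arrays[0])
        pdb_file.lines = (["MODEL        1"] + pdb_file.lines + ["ENDMDL"])
    else:
        stack = bst.stack(arrays)
        pdb_file.set_structure(stack)
    if hasattr(sink, "write"):
        pdb_file.write(sink)
    else:
        with open(sink, "w") as fh:
            pdb_file.write(fh)


def truncate(conf: Conformation, first: int, last: int,
             chain: str | None = None) -> Conformation:
    """Restrict to residues with first <= number <= last on one chain.

    Other chains (e.g. a bound peptide) are preserved untouched.
    """
    if first > last:
        raise ValueError("first must be <= last")
    if chain is None:
        chain = conf.residues[0].chain
    if chain not in conf.chains:
        raise StructureError(f"chain {chain!r} not present")
    kept = [r.copy() for r in conf.residues
            if r.chain != chain or first <= r.number <= last]
    if not any(r.chain == chain and first <= r.number <= last for r in kept):
        raise StructureError(
            f"no residues in range {first}-{last} on chain {chain!r}")
    return Conformation(kept, tag=conf.tag)


_SUB_RE = re.compile(r"^([ACGU])(\d+)([ACGU])$")
_DEL_RE = re.compile(r"^del([ACGU])(\d+)$")


def parse_mutation(spec: str) -> list[tuple[str, str, int, str | None]]:
    """Parse a mutation string like ``"U40C"``, ``"delU63"`` or ``"A39G+U68C"``.

    Returns a list of (kind, from_base, number, to_base) tuples with kind
    in {"sub", "del"} (to_base is None for deletions).
    """
    ops = []
    for part in spec.replace(" ", "").split("+"):
        m = _SUB_RE.match(part)
        if m:
            ops.append(("sub", m.group(1), int(m.group(2)), m.group(3)))
            continue
        m = _DEL_RE.match(part)
        if m:
            ops.append(("del", m.group(1), int(m.group(2)), None))
            continue
        raise ValueError(f"cannot parse mutation component {part!r}")
    return ops


def _attachment_frame(gly: np.ndarray, c1p: np.ndarray, ref: np.ndarray
                      ) -> np.ndarray:
    """Right-handed frame from glycosidic N, C1' and an in-plane ring atom."""
    x = c1p - gly
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise StructureError("degenerate glycosidic geometry")
    x = x / nx
    v = ref - gly
    y = v - np.dot(v, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-6:
        raise StructureError("degenerate attachment frame")
    y = y / ny
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _rebuild_base(res: Residue, new_base: str) -> None:
    """Replace the base moiety in-place with an ideal template of new_base.

    The template is superposed on the attachment frame defined by the
    glycosidic nitrogen, C1' and the ring neighbour of the glycosidic
    nitrogen, leaving sugar and backbone atoms untouched.
    """
    old_base = res.name
    gly_name = chemdata.GLYCOSIDIC_ATOM[old_base]
    ref_name = chemdata.FRAME_REFERENCE_ATOM[old_base]
    for needed in (gly_name, "C1'", ref_name):
        if not res.has_atom(needed):
            raise StructureError(
                f"residue {old_base}{res.number}: cannot mutate, missing {needed}")
    gly = res.atom(gly_name).position
    c1p = res.atom("C1'").position
    ref = res.atom(ref_name).position
    frame_old = _attachment_frame(gly, c1p, ref)

    tmpl = chemdata.base_template(new_base)
    t_gly = tmpl[chemdata.GLYCOSIDIC_ATOM[new_base]]
    t_ref = tmpl[chemdata.FRAME_REFERENCE_ATOM[new_base]]
    t_c1p = tmpl["C1'"]
    frame_new = _attachment_frame(t_gly, t_c1p, t_ref)
    R = frame_old @ frame_new.T

    old_base_atoms = set(chemdata.base_atom_names(old_base))
    kept = [a for a in res.atoms if a.name not in old_base_atoms]
    serial = max((a.serial for a in res.atoms), default=0)
    new_atoms = []
    for name in chemdata.base_atom_names(new_base):
        serial += 1
        pos = R @ (tmpl[name] - t_gly) + gly
        new_atoms.append(Atom(name, name[0], pos, serial))
    res.atoms = kept + new_atoms
    res.name = new_base


def apply_mutation(conf: Conformation, spec: str,
                   chain: str | None = None) -> Conformation:
    """Apply substitutions / deletions given as e.g. ``"U40C"`` or ``"delU63"``.

    Substitutions rebuild the base moiety from an ideal template on the
    glycosidic attachment frame; deletions remove the residue without
    renumbering anything.  Non-target residues are untouched.
    """
    ops = parse_mutation(spec)
    out = conf.copy()
    for kind, from_base, number, to_base in ops:
        res = out.residue(number, chain)
        if res.name != from_base:
            raise StructureError(
                f"mutation {spec!r}: residue {number} is {res.name}, "
                f"expected {from_base}")
        if kind == "del":
            out.residues.remove(res)
        else:
            _rebuild_base(res, to_base)
    if not out.residues:
        raise StructureError("mutation removed every residue")
    return out
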