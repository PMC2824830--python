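"""Reading and writing macromolecular coordinate files (PDB / mmCIF).

Parsing is delegated to biotite; this module converts to the pipeline's atom
records, resolves alternate locations to the highest-occupancy conformer,
extracts cell + space-group metadata and symmetry operators (from the file
when present, else from the internal space-group table), and separates
monoatomic cations from drugs and waters.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure

from .model import AtomRecord, CrystalModel, UnitCell
from .spacegroups import operators_for, parse_xyz_op

logger = logging.getLogger(__name__)

__all__ = ["read_structure", "write_structure", "StructureFormatError"]


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed in the declared dialect."""


def read_structure(path, dialect: str = "auto") -> CrystalModel:
    """Read a PDB or mmCIF file into a :class:`CrystalModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order); only the first model of multi-model files is
    used.  Hydrogens are dropped: all downstream contact criteria are heavy-
    atom distances.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if dialect == "pdb":
        array, cell, ops = _read_pdb(path)
    elif dialect == "mmcif":
        array, cell, ops = _read_mmcif(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    array = array[array.element != "H"]
    atoms = _to_records(array)
    model = CrystalModel(atoms=atoms, cell=cell, operators=ops, source=str(path))
    return model


def _read_pdb(path):
    try:
        pdb = PDBFile.read(str(path))
        array = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:  # biotite raises various parse errors
        raise StructureFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    sg = "P 1"
    try:
        info = pdb.get_space_group()
        if info is not None and str(info.space_group).strip():
            sg = str(info.space_group).strip()
    except Exception:
        pass
    cell = _cell_from_box(array.box, sg) if array.box is not None else None
    ops = _operators_from_symbol(cell)
    return array, cell, ops


def _cell_from_box(box, space_group):
    a, b, c, alpha, beta, gamma = struc.unitcell_from_vectors(
        np.asarray(box, dtype=float)
    )
    return UnitCell(
        a=float(a), b=float(b), c=float(c),
        alpha=float(np.rad2deg(alpha)), beta=float(np.rad2deg(beta)),
        gamma=float(np.rad2deg(gamma)),
        space_group=str(space_group).strip(),
    )


def _read_mmcif(path):
    try:
        cif = CIFFile.read(str(path))
        block = cif.block
        array = cif_get_structure(
            cif, model=1, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:
        raise StructureFormatError(f"cannot parse {path} as mmCIF: {exc}") from exc
    cell = None
    sg = "P 1"
    if "symmetry" in block:
        cat = block["symmetry"]
        if "space_group_name_H-M" in cat:
            sg = cat["space_group_name_H-M"].as_item()
    if "cell" in block:
        cat = block["cell"]
        try:
            cell = UnitCell(
                a=float(cat["length_a"].as_item()),
                b=float(cat["length_b"].as_item()),
                c=float(cat["length_c"].as_item()),
                alpha=float(cat["angle_alpha"].as_item()),
                beta=float(cat["angle_beta"].as_item()),
                gamma=float(cat["angle_gamma"].as_item()),
                space_group=sg,
            )
        except (KeyError, ValueError):
            cell = None
    ops = _operators_from_file(block)
    if not ops:
        ops = _operators_from_symbol(cell)
    return array, cell, ops


def _operators_from_file(block):
    for cat_name, col in (
        ("space_group_symop", "operation_xyz"),
        ("symmetry_equiv", "pos_as_xyz"),
    ):
        if cat_name in block:
            cat = block[cat_name]
            if col in cat:
                labels = np.atleast_1d(cat[col].as_array(str))
                return [parse_xyz_op(lab) for lab in labels]
    return []


def _operators_from_symbol(cell):
    if cell is None:
        return []
    try:
        return operators_for(cell.space_group)
    except KeyError:
        return []


def require_operators(model: CrystalModel) -> None:
    """Raise if no symmetry operators could be determined for the model."""
    if not model.operators:
        sg = model.cell.space_group if model.cell else "<no cell>"
        raise ValueError(
            f"symmetry operators unavailable for {model.source or 'model'}: "
            f"space group {sg!r} is not in the internal table and the file "
            "carries no explicit operators"
        )


def _to_records(array) -> list[AtomRecord]:
    n = array.array_length()
    occ = (
        array.occupancy
        if "occupancy" in array.get_annotation_categories()
        else np.ones(n)
    )
    serial = (
        array.atom_id
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    ins = (
        array.ins_code
        if "ins_code" in array.get_annotation_categories()
        else np.full(n, "")
    )
    records = []
    for i in range(n):
        records.append(
            AtomRecord(
                serial=int(serial[i]),
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                residue_name=str(array.res_name[i]),
                chain_id=str(array.chain_id[i]),
                residue_number=int(array.res_id[i]),
                position=array.coord[i],
                insertion_code=str(ins[i]),
                occupancy=float(min(max(occ[i], 0.0), 1.0)),
                is_hetero=bool(array.hetero[i]),
            )
        )
    return records


def write_structure(model: CrystalModel, path) -> None:
    """Write the model as a standard PDB file with a CRYST1 record.

    A model without a cell is written as P 1 with a dummy 1 Å cell and a
    warning, so the file remains valid PDB.
    """
    path = Path(path)
    atoms = model.atoms
    array = struc.AtomArray(len(atoms))
    array.coord = np.array([a.position for a in atoms], dtype=np.float32)
    array.atom_name = np.array([a.name for a in atoms])
    array.res_name = np.array([a.residue_name for a in atoms])
    array.chain_id = np.array([a.chain_id for a in atoms])
    array.res_id = np.array([a.residue_number for a in atoms])
    array.element = np.array([a.element.upper() for a in atoms])
    array.hetero = np.array([a.is_hetero for a in atoms])
    array.add_annotation("occupancy", float)
    array.occupancy = np.array([a.occupancy for a in atoms])
    array.add_annotation("atom_id", int)
    array.atom_id = np.array([a.serial for a in atoms])

    cell = model.cell
    if cell is None:
        warnings.warn("model has no unit cell; writing dummy 1 Å P 1 cell")
        logger.warning("model has no unit cell; writing dummy 1 Å P 1 cell")
        cell = UnitCell(1.0, 1.0, 1.0, 90.0, 90.0, 90.0, "P 1")
    array.box = struc.vectors_from_unitcell(
        cell.a, cell.b, cell.c,
        np.deg2rad(cell.alpha), np.deg2rad(cell.beta), np.deg2rad(cell.gamma),
    )
    pdb = PDBFile()
    pdb.set_structure(array)
    try:
        pdb.set_space_group(SimpleNamespace(space_group=cell.space_group, z_val=1))
    except Exception:
        logger.warning("could not encode space group %r in CRYST1", cell.space_group)
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write structure to {path}: {exc}") from exc
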