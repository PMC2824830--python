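"""Crystallographic symmetry expansion: rebuild the packing neighbours of the
asymmetric unit so lattice crossovers can be analysed.

Every space-group operator is combined with integer lattice shifts; a copy is
kept when at least one of its nucleic-acid atoms comes within the contact
radius of any asymmetric-unit atom.  Transforms are applied in the orthogonal
Å frame, so each copy is an exact isometry of the source (rigidity is a
tested invariant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, CrystalModel, SymmetryOperator, UnitCell
from .io import require_operators

#: Default contact radius (Å).  Inter-axial separations of juxtaposed B-DNA
#: duplexes are ≤ ~22 Å; margin added for atoms off the axis.
DEFAULT_CONTACT_RADIUS = 25.0


def orthogonalization(cell: UnitCell) -> np.ndarray:
    """Fractional → orthogonal (Å) matrix, standard crystallographic setting.

    Cell axis **a** lies along x, **b** in the xy-plane; det equals the cell
    volume.
    """
    alpha, beta, gamma = (np.deg2rad(x) for x in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg, sg = np.cos(alpha), np.cos(beta), np.cos(gamma), np.sin(gamma)
    v = cell.volume  # raises on degenerate cells
    cz = v / (cell.a * cell.b * sg)
    return np.array([
        [cell.a, cell.b * cg, cell.c * cb],
        [0.0, cell.b * sg, cell.c * (ca - cb * cg) / sg],
        [0.0, 0.0, cz],
    ])


@dataclass
class PlacedCopy:
    """A symmetry image of the asymmetric unit's nucleic content.

    ``transform`` is the rigid transform ``x -> R x + t`` in the orthogonal
    frame; provenance (operator label + lattice shift) is carried into all
    downstream reports.
    """

    source_chain_ids: frozenset
    operator: SymmetryOperator
    lattice_shift: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    atoms: list[AtomRecord] = field(default_factory=list)
    is_identity: bool = False

    @property
    def label(self) -> str:
        i, j, k = (int(x) for x in self.lattice_shift)
        return f"{self.operator.label}|{i},{j},{k}"

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def orthogonal_transform(
    cell: UnitCell, op: SymmetryOperator, shift
) -> tuple[np.ndarray, np.ndarray]:
    """Operator + lattice shift as a rigid transform in the orthogonal frame."""
    om = orthogonalization(cell)
    om_inv = np.linalg.inv(om)
    rot = om @ op.rotation @ om_inv
    trans = om @ (op.translation + np.asarray(shift, dtype=float))
    return rot, trans


def expand_neighborhood(
    model: CrystalModel, radius: float = DEFAULT_CONTACT_RADIUS
) -> list[PlacedCopy]:
    """Generate all distinct symmetry copies of the nucleic chains (plus ions)
    with at least one atom within ``radius`` of the asymmetric unit.

    The identity/zero-shift copy is always included (flagged
    ``is_identity``); duplicate transforms are removed at 1e-6 Å.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    require_operators(model)
    if model.cell is None:
        raise ValueError("model has no unit cell")

    source_atoms = [
        a for ats in model.nucleic_chains.values() for a in ats
    ] + list(model.ions)
    if not source_atoms:
        return []
    src_coords = np.array([a.position for a in source_atoms])
    chain_ids = frozenset(model.nucleic_chains)

    om = orthogonalization(model.cell)
    tree = cKDTree(model.coords())

    # Lattice shift bound: enough cells to cover radius + AU extent along the
    # shortest axis projection (tested against brute force enumeration).
    spans = np.linalg.norm(om, axis=0)
    heights = _cell_heights(om)
    extent = np.linalg.norm(src_coords.max(0) - src_coords.min(0))
    bound = np.ceil((radius + extent) / heights).astype(int) + 1

    all_coords = model.coords()
    au_center = all_coords.mean(axis=0)
    au_radius = np.linalg.norm(all_coords - au_center, axis=1).max()
    src_center = src_coords.mean(axis=0)
    src_radius = np.linalg.norm(src_coords - src_center, axis=1).max()

    copies: list[PlacedCopy] = []
    seen: list[tuple[np.ndarray, np.ndarray]] = []
    shifts = itertools.product(*(range(-b, b + 1) for b in bound))
    for shift in shifts:
        for op in model.operators:
            rot, trans = orthogonal_transform(model.cell, op, shift)
            identity = np.allclose(rot, np.eye(3), atol=1e-9) and np.allclose(
                trans, 0.0, atol=1e-9
            )
            if not identity:
                # bounding-sphere prescreen before the exact KD-tree query
                sep = np.linalg.norm(rot @ src_center + trans - au_center)
                if sep > radius + au_radius + src_radius:
                    continue
            moved = src_coords @ rot.T + trans
            if not identity:
                dmin = tree.query(moved, k=1)[0].min()
                if dmin > radius:
                    continue
            if any(
                np.allclose(rot, r0, atol=1e-9) and np.allclose(trans, t0, atol=1e-6)
                for r0, t0 in seen
            ):
                continue
            seen.append((rot, trans))
            atoms = [a.moved(p) for a, p in zip(source_atoms, moved)]
            copies.append(
                PlacedCopy(
                    source_chain_ids=chain_ids,
                    operator=op,
                    lattice_shift=np.asarray(shift, dtype=int),
                    rotation=rot,
                    translation=trans,
                    atoms=atoms,
                    is_identity=identity,
                )
            )
    # identity copy first for stable provenance ordering
    copies.sort(key=lambda c: (not c.is_identity, c.label))
    return copies


def _cell_heights(om: np.ndarray) -> np.ndarray:
    """Perpendicular heights of the unit cell along each axis direction."""
    a, b, c = om[:, 0], om[:, 1], om[:, 2]
    vol = abs(np.linalg.det(om))
    return np.array([
        vol / np.linalg.norm(np.cross(b, c)),
        vol / np.linalg.norm(np.cross(c, a)),
        vol / np.linalg.norm(np.cross(a, b)),
    ])
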