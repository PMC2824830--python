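"""Core coordinate-model types: atoms, unit cells, symmetry operators, crystal models.

The pipeline works on plain atom records grouped into nucleic chains, plus the
crystallographic metadata (cell, space-group operators) needed to rebuild
lattice neighbours.  Protein atoms (e.g. histones of nucleosome core
particles) are carried in ``atoms`` but are not part of ``nucleic_chains``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# Residue names accepted as nucleotides, mapped to a one-letter base code.
# I = inosine (pairs like G without the 2-amino group); 5CM/5MC = 5-methylcytosine.
NUCLEOTIDE_LETTERS = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T", "I": "I",
    "5CM": "C", "5MC": "C", "CM5": "C", "BRU": "U", "5IU": "U",
    "1AP": "A", "2PR": "A", "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}

PURINE_LETTERS = {"A", "G", "I"}
PYRIMIDINE_LETTERS = {"C", "T", "U"}

# Monoatomic cation residues by charge class.  Co covers the metal centre of
# hexammine-cobalt(III) sites (residue NCO), treated as a single cation site.
DIVALENT_METALS = {"MG", "CA", "MN", "ZN", "SR", "BA", "CD", "NI", "CU"}
MONOVALENT_METALS = {"NA", "K", "LI", "RB", "CS", "TL"}
OTHER_METALS = {"CO"}
CATION_ELEMENTS = DIVALENT_METALS | MONOVALENT_METALS | OTHER_METALS

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(slots=True)
class AtomRecord:
    """One heavy atom of the model, positions in the orthogonal frame (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    insertion_code: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial} {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            self.element = infer_element(self.name)
        self.element = self.element.strip().capitalize()

    def moved(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (heavy atoms only)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in CATION_ELEMENTS or two in {"FE", "CL", "BR"}:
        return two.capitalize()
    return stripped[0].upper()


@dataclass(slots=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        """Closed-form triclinic cell volume."""
        ca, cb, cg = (np.cos(np.deg2rad(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")
        return self.a * self.b * self.c * float(np.sqrt(arg))


@dataclass(slots=True)
class SymmetryOperator:
    """Space-group operator in the fractional frame."""

    rotation: np.ndarray
    translation: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        det = np.linalg.det(self.rotation)
        if abs(abs(det) - 1.0) > 1e-6:
            raise ValueError(f"operator rotation determinant {det} is not ±1")

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=1e-9)
            and np.allclose(self.translation % 1.0, 0.0, atol=1e-9)
        )


@dataclass
class CrystalModel:
    """Parsed asymmetric unit plus crystal metadata.

    ``nucleic_chains`` maps chain id to the atom records of nucleotide
    residues in that chain; ``ions`` holds monoatomic cation sites (each also
    present in ``atoms``).  Non-ion heteroatoms such as bound drugs are kept
    in ``atoms`` but excluded from the DNA-DNA contact analysis.
    """

    atoms: list[AtomRecord]
    cell: Optional[UnitCell] = None
    operators: list[SymmetryOperator] = field(default_factory=list)
    nucleic_chains: dict[str, list[AtomRecord]] = field(default_factory=dict)
    ions: list[AtomRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not self.nucleic_chains and not self.ions:
            self.classify_entities()

    def classify_entities(self) -> None:
        """Group atoms into nucleic chains and extract cation sites."""
        chains: dict[str, list[AtomRecord]] = {}
        ions: list[AtomRecord] = []
        for atom in self.atoms:
            res = atom.residue_name.strip().upper()
            if res in WATER_NAMES:
                continue
            if _is_cation_site(atom):
                ions.append(atom)
                continue
            if res in NUCLEOTIDE_LETTERS or _looks_like_nucleotide(res):
                chains.setdefault(atom.chain_id, []).append(atom)
        # nucleotide fallback needs the residue's atom inventory, re-filter:
        self.nucleic_chains = {
            cid: ats for cid, ats in chains.items() if _has_complete_nucleotide(ats)
        }
        self.ions = ions

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def nucleic_coords(self) -> np.ndarray:
        pts = [a.position for ats in self.nucleic_chains.values() for a in ats]
        return np.array(pts, dtype=float)


def _is_cation_site(atom: AtomRecord) -> bool:
    """True for the metal atom of a monoatomic (or hexammine) cation residue.

    Water oxygens and drug atoms never qualify: the element itself must be a
    metal from the cation table.
    """
    elem = atom.element.upper()
    res = atom.residue_name.strip().upper()
    if elem not in CATION_ELEMENTS:
        return False
    # metal residue names: MG, CA, MN, NA, K, ZN ... or NCO (hexammine Co)
    return res in CATION_ELEMENTS or res in {"NCO", "3CO", "CO"}


def cation_charge_class(atom: AtomRecord) -> str:
    elem = atom.element.upper()
    if elem in DIVALENT_METALS:
        return "divalent"
    if elem in MONOVALENT_METALS:
        return "monovalent"
    return "other"


def _looks_like_nucleotide(res_name: str) -> bool:
    # permissive hook for modified residues; resolved properly per-residue in
    # duplex detection where the atom inventory is available
    return res_name in NUCLEOTIDE_LETTERS


def _has_complete_nucleotide(atoms: list[AtomRecord]) -> bool:
    names = {a.name.strip() for a in atoms}
    return "C1'" in names or "C1*" in names


def base_letter(res_name: str) -> Optional[str]:
    return NUCLEOTIDE_LETTERS.get(res_name.strip().upper())
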