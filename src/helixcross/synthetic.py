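"""Synthetic B-DNA constructs: ideal duplexes, posed chiral crossovers,
mirror perturbations, and mock crystals.

The builder is a coarse fiber model.  Base pairs are planar and stacked with
a fixed twist and rise about the axis through the C1' midpoints; in-plane
base geometry comes from the chemical component dictionary's ideal
nucleotides (via biotite), posed onto standard base-pair reference-frame
anchor coordinates, so Watson-Crick hydrogen-bond distances (2.9-3.1 Å) and
the C1'-C1' separation (10.8 Å) are chemically correct.  Sugars are attached
by rigid superposition of the ideal nucleotide on its placed base; the
5'-phosphate is placed analytically on the backbone helix (position tuned
once for O5'-P / O3'-P connectivity).  The model has no sequence-dependent
fine structure (propeller, slide, roll): it is a fixture generator whose
ground truth (axis, twist, crossing angle, interaction mode) is exact by
construction, not a refinement-grade DNA model.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass


import numpy as np
import biotite.structure.info as _ccd_info

from .model import AtomRecord, CrystalModel, UnitCell
from .spacegroups import operators_for
from . import io as _io
from .duplex import (
    Duplex,
    PURINE_RING,
    PYRIMIDINE_RING,
    build_duplex,
)

C1P = "C1'"

#: Standard base-pair reference-frame anchor coordinates (Å, in-plane):
#: x toward the major groove, y toward the strand-I C1'.  These anchor the
#: pose of each base within the pair plane; the chemically exact in-plane
#: geometry itself comes from the CCD ideal nucleotides fitted onto them.
_ANCHORS: dict[str, dict[str, tuple[float, float]]] = {
    "G": {"N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
          "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
          "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
          "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), C1P: (-2.477, 5.399)},
    "A": {"N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
          "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
          "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
          "C4": (-1.267, 3.124), C1P: (-2.479, 5.346)},
    "C": {"N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
          "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
          "C5": (1.056, 4.275), "C6": (-0.023, 5.068), C1P: (-2.477, 5.402)},
    "T": {"N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
          "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
          "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
          C1P: (-2.481, 5.354)},
}

#: letter -> (residue name, anchor set to fit against, complement letter)
LETTERS: dict[str, tuple[str, str, str]] = {
    "A": ("DA", "A", "T"),
    "T": ("DT", "T", "A"),
    "G": ("DG", "G", "C"),
    "C": ("DC", "C", "G"),
    "U": ("DU", "T", "A"),
    "I": ("DI", "G", "C"),
    "M": ("5CM", "C", "G"),
}

SUGAR_ATOMS = ["C2'", "C3'", "C4'", "C5'", "O3'", "O4'", "O5'"]

#: Analytic 5'-phosphate site in the local pair frame (strand I):
#: cylindrical radius (Å), azimuth (deg; C1' sits at 90°), z offset (Å).
#: Solved once, jointly with the glycosidic torsion below, for backbone
#: continuity (O5'(i)-P(i) and O3'(i-1)-P(i) ≈ 1.6-2.0 Å) at the default
#: 36°/3.38 Å stacking.
P_RADIUS = 8.44
P_AZIMUTH_DEG = 78.9
P_DZ = -1.15
OP_BOND = 1.48
OP_SPLAY_DEG = 55.0


@dataclass(frozen=True)
class BuildParams:
    """Parameters of an ideal straight duplex."""

    sequence: str
    twist_deg_per_step: float = 36.0
    rise_per_step: float = 3.38
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        seq = self.sequence.upper()
        unknown = set(seq) - set(LETTERS)
        if unknown:
            raise ValueError(f"unknown base letters {sorted(unknown)}")
        if not (20.0 < self.twist_deg_per_step < 45.0):
            raise ValueError("twist outside (20, 45) degrees")
        if not (2.5 < self.rise_per_step < 4.5):
            raise ValueError("rise outside (2.5, 4.5) Å")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class CrossoverSpec:
    """A designed two-duplex crossover."""

    alpha_deg: float
    interaxial_distance: float
    mode_template: str = "none"
    sequences: tuple[str, str] = ("ACCGGCGCCACA", "ACCGGCGCCACA")

    def __post_init__(self):
        if not (-90.0 < self.alpha_deg <= 90.0):
            raise ValueError("alpha must lie in (-90, 90]")
        if self.interaxial_distance <= 0:
            raise ValueError("distance must be positive")
        if self.mode_template not in (
            "groove_backbone_major", "groove_groove_major",
            "groove_groove_minor", "none",
        ):
            raise ValueError(f"unknown mode template {self.mode_template!r}")


@dataclass
class BuiltDuplex:
    """An ideal duplex plus its construction ground truth."""

    atoms: list[AtomRecord]
    params: BuildParams
    axis_point: np.ndarray
    axis_direction: np.ndarray
    pair_origins: np.ndarray
    chain_ids: tuple[str, str] = ("A", "B")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        for a, p in zip(self.atoms, coords):
            a.position = np.asarray(p, dtype=float)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        self.set_coords(self.coords() @ np.asarray(rotation).T + translation)
        self.axis_point = rotation @ self.axis_point + translation
        self.axis_direction = np.asarray(rotation) @ self.axis_direction
        self.pair_origins = self.pair_origins @ np.asarray(rotation).T + translation

    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def to_duplex(self) -> Duplex:
        ca, cb = self.chain_ids
        chains = self.chains()
        dup = build_duplex(chains[ca], chains[cb], source=(("built", ca), ("built", cb)))
        if dup is None:
            raise RuntimeError("built duplex failed base-pair detection")
        return dup


@functools.lru_cache(maxsize=None)
def _planar_template(res_name: str) -> dict[str, np.ndarray]:
    """In-plane (2D) coordinates of the base atoms + C1' of a CCD ideal
    nucleotide, from an SVD plane fit of the ring."""
    res = _ccd_info.residue(res_name)
    res = res[res.element != "H"]
    names = list(res.atom_name)
    ring = [n for n in PURINE_RING + PYRIMIDINE_RING if n in names]
    base_like = [
        n for n in names
        if not n.endswith("'") and n not in ("P", "OP1", "OP2", "OP3")
    ] + [C1P]
    X = res.coord.astype(float)
    pts = np.array([X[names.index(n)] for n in ring])
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    e1, e2 = vt[0], vt[1]
    return {
        n: np.array([ (X[names.index(n)] - center) @ e1,
                      (X[names.index(n)] - center) @ e2 ])
        for n in base_like if n in names
    }


def _ring_signed_area(coords2d: dict[str, np.ndarray], ring: list[str]) -> float:
    pts = [coords2d[n] for n in ring if n in coords2d]
    area = 0.0
    for k in range(len(pts)):
        x0, y0 = pts[k]
        x1, y1 = pts[(k + 1) % len(pts)]
        area += x0 * y1 - x1 * y0
    return 0.5 * area


@functools.lru_cache(maxsize=None)
def _strand_i_pose(letter: str) -> dict[str, np.ndarray]:
    """Base atoms + C1' of ``letter`` posed in the pair plane as strand I.

    The planar template's view side (arbitrary from the plane projection) is
    first canonicalised to the anchors' chirality, so the subsequent proper
    2D superposition leaves the deoxyribose on the natural side of the base
    plane when the full nucleotide is later rigid-fitted in 3D.
    """
    res_name, anchor_key, _ = LETTERS[letter]
    tmpl = dict(_planar_template(res_name))
    anchors = _ANCHORS[anchor_key]
    ring = PURINE_RING if anchor_key in ("G", "A") else PYRIMIDINE_RING
    ring = [n for n in ring if n in tmpl and n in anchors]
    if _ring_signed_area(tmpl, ring) * _ring_signed_area(anchors_np := {
        n: np.asarray(v, dtype=float) for n, v in anchors.items()
    }, ring) < 0:
        tmpl = {n: np.array([v[0], -v[1]]) for n, v in tmpl.items()}
    shared = [n for n in tmpl if n in anchors]
    src = np.array([tmpl[n] for n in shared])
    dst = np.array([anchors_np[n] for n in shared])
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    U, _, Vt = np.linalg.svd((src - sc).T @ (dst - dc))
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = dc - R @ sc
    return {n: R @ v + t for n, v in tmpl.items()}


@functools.lru_cache(maxsize=None)
def _pair_layout(letter: str) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Strand-I and strand-II base atom positions of the pair led by
    ``letter``, shifted so the C1' midpoint is exactly at the origin."""
    partner = LETTERS[letter][2]
    pose_i = _strand_i_pose(letter)
    pose_ii = {n: np.array([v[0], -v[1]]) for n, v in _strand_i_pose(partner).items()}
    mid = 0.5 * (pose_i[C1P] + pose_ii[C1P])
    pose_i = {n: v - mid for n, v in pose_i.items()}
    pose_ii = {n: v - mid for n, v in pose_ii.items()}
    return pose_i, pose_ii


@functools.lru_cache(maxsize=None)
def _ccd_heavy(res_name: str) -> tuple[list[str], np.ndarray]:
    res = _ccd_info.residue(res_name)
    res = res[(res.element != "H") & (res.atom_name != "OP3")]
    return list(res.atom_name), res.coord.astype(float)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper-rotation rigid superposition src -> dst."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    U, _, Vt = np.linalg.svd((src - sc).T @ (dst - dc))
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, dc - R @ sc


#: Glycosidic torsion target (deg), O4'-C1'-N9-C4 (purines) /
#: O4'-C1'-N1-C2 (pyrimidines).  Solved jointly with the phosphate site for
#: backbone continuity given the CCD ideal-sugar conformer; with that pucker
#: the canonical anti torsion cannot close the chain, so the builder trades
#: torsional purity for a connected, regularly placed backbone (the pipeline
#: consumes base geometry and phosphate positions, not torsion profiles).
CHI_TARGET_DEG = 18.2


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.degrees(np.arctan2(np.cross(v, w) @ b1, v @ w)))


def _rotate_about(points: dict[str, np.ndarray], origin, axis, angle_deg) -> dict[str, np.ndarray]:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return {n: R @ (p - origin) + origin for n, p in points.items()}


def _sugar_positions(
    res_name: str, placed_base: dict[str, np.ndarray], is_purine: bool
) -> dict[str, np.ndarray]:
    """Rigid-fit the CCD ideal nucleotide onto its placed base, then set the
    glycosidic torsion to the B-DNA anti value (the CCD conformer's χ is
    arbitrary, which would scatter the backbone)."""
    names, coords = _ccd_heavy(res_name)
    shared = [n for n in placed_base if n in names]
    src = np.array([coords[names.index(n)] for n in shared])
    dst = np.array([placed_base[n] for n in shared])
    R, t = _kabsch(src, dst)
    sugar = {
        n: R @ coords[names.index(n)] + t
        for n in SUGAR_ATOMS if n in names
    }
    n_gly = "N9" if is_purine else "N1"
    c_ref = "C4" if is_purine else "C2"
    c1p, ngly, cref = placed_base[C1P], placed_base[n_gly], placed_base[c_ref]
    chi = _dihedral(sugar["O4'"], c1p, ngly, cref)
    delta = CHI_TARGET_DEG - chi
    rotated = _rotate_about(sugar, c1p, ngly - c1p, delta)
    new_chi = _dihedral(rotated["O4'"], c1p, ngly, cref)
    if abs((new_chi - CHI_TARGET_DEG + 180) % 360 - 180) > 1e-6:
        rotated = _rotate_about(sugar, c1p, ngly - c1p, -delta)
    return rotated


def build_ideal_bdna(params: BuildParams, chain_ids=("A", "B")) -> BuiltDuplex:
    """Construct an ideal straight B-form duplex along +z.

    Pair i sits at z = i·rise, twisted by i·twist about +z; the C1' midpoints
    (pair origins) lie exactly on the z-axis, which is returned as the
    ground-truth axis.  Optional seeded isotropic Gaussian coordinate noise.
    """
    seq = params.sequence
    n = len(seq)
    rise, twist = params.rise_per_step, np.deg2rad(params.twist_deg_per_step)
    strand_i: list[AtomRecord] = []
    strand_ii: list[AtomRecord] = []
    serial = [1]

    def emit(bucket, name, pos3, res_name, chain, res_num):
        bucket.append(AtomRecord(
            serial=serial[0], name=name, element="",
            residue_name=res_name, chain_id=chain, residue_number=res_num,
            position=pos3,
        ))
        serial[0] += 1

    for i, letter in enumerate(seq):
        res_i_name = LETTERS[letter][0]
        partner_letter = LETTERS[letter][2]
        res_ii_name = LETTERS[partner_letter][0]
        pose_i, pose_ii = _pair_layout(letter)
        cos_t, sin_t = np.cos(i * twist), np.sin(i * twist)
        Rz = np.array([[cos_t, -sin_t, 0.0], [sin_t, cos_t, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, i * rise])

        def place2d(v2, dz=0.0):
            return Rz @ np.array([v2[0], v2[1], dz]) + shift

        # strand I residue i+1 (5'->3' ascending z)
        base_3d = {nme: place2d(v) for nme, v in pose_i.items()}
        sugar = _sugar_positions(res_i_name, base_3d, letter in ("A", "G", "I"))
        phos = _phosphate_site(Rz, shift, strand="I")
        for nme, p in {**base_3d, **sugar, **phos}.items():
            emit(strand_i, nme, p, res_i_name, chain_ids[0], i + 1)

        # strand II residue n-i (its own 5'->3' runs toward -z)
        base_3d = {nme: place2d(v) for nme, v in pose_ii.items()}
        sugar = _sugar_positions(res_ii_name, base_3d, partner_letter in ("A", "G", "I"))
        phos = _phosphate_site(Rz, shift, strand="II")
        for nme, p in {**base_3d, **sugar, **phos}.items():
            emit(strand_ii, nme, p, res_ii_name, chain_ids[1], n - i)

    strand_ii.sort(key=lambda a: (a.residue_number, a.serial))
    atoms = strand_i + strand_ii
    origins = np.array([[0.0, 0.0, i * rise] for i in range(n)])
    center = origins.mean(axis=0)
    for a in atoms:
        a.position = a.position - center
    origins = origins - center

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        for a in atoms:
            a.position = a.position + rng.normal(0.0, params.noise_sigma, 3)

    return BuiltDuplex(
        atoms=atoms,
        params=params,
        axis_point=np.zeros(3),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        pair_origins=origins,
        chain_ids=tuple(chain_ids),
    )


def _phosphate_site(Rz: np.ndarray, shift: np.ndarray, strand: str) -> dict[str, np.ndarray]:
    """Analytic 5'-phosphate group (P, OP1, OP2) on the backbone helix."""
    az = np.deg2rad(P_AZIMUTH_DEG)
    local = np.array([P_RADIUS * np.cos(az), P_RADIUS * np.sin(az), P_DZ])
    if strand == "II":
        local = np.array([local[0], -local[1], -local[2]])
    p = Rz @ local + shift
    radial = Rz @ np.array([np.cos(az), np.sin(az) if strand == "I" else -np.sin(az), 0.0])
    radial = np.array([radial[0], radial[1], 0.0])
    radial /= np.linalg.norm(radial)
    zhat = np.array([0.0, 0.0, 1.0])
    splay = np.deg2rad(OP_SPLAY_DEG)
    op1 = p + OP_BOND * (radial * np.cos(splay) + zhat * np.sin(splay))
    op2 = p + OP_BOND * (radial * np.cos(splay) - zhat * np.sin(splay))
    return {"P": p, "OP1": op1, "OP2": op2}


def mirror_assembly(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Reflect through the yz-plane (x -> -x): an improper isometry that
    preserves all distances and negates every signed crossing angle."""
    return [a.moved(a.position * np.array([-1.0, 1.0, 1.0])) for a in atoms]


@dataclass
class BuiltCrossover:
    duplex_a: BuiltDuplex
    duplex_b: BuiltDuplex
    spec: CrossoverSpec

    def atoms(self) -> list[AtomRecord]:
        return self.duplex_a.atoms + self.duplex_b.atoms

    def chains(self) -> list[tuple[tuple, list[AtomRecord]]]:
        out = []
        for built in (self.duplex_a, self.duplex_b):
            for cid, ats in built.chains().items():
                out.append((("built", cid), ats))
        return out


def build_crossover(spec: CrossoverSpec, noise_sigma: float = 0.0, seed: int = 0) -> BuiltCrossover:
    """Pose two ideal duplexes at the requested signed crossing angle and
    inter-axial distance.

    Duplex A runs along +z through the origin; duplex B is rotated by alpha
    about +x (the inter-axial normal) and shifted to (d, 0, 0).  For mode
    templates both duplexes are first rolled about their own axes so the
    requested faces meet: A's chosen groove points at B, and B presents
    either its backbone phosphates (groove_backbone) or a groove floor
    (groove_groove) to A.  The measured signed crossing angle and distance
    equal the spec exactly by construction.
    """
    da = build_ideal_bdna(BuildParams(spec.sequences[0]), chain_ids=("A", "B"))
    db = build_ideal_bdna(BuildParams(spec.sequences[1]), chain_ids=("C", "D"))

    tmpl = spec.mode_template
    if tmpl != "none":
        if spec.interaxial_distance < 10.0:
            warnings.warn(
                "inter-axial distance < 10 Å with a groove template causes "
                "steric clashes; building anyway"
            )
        a_groove = "minor" if tmpl == "groove_groove_minor" else "major"
        _roll_to(da, _groove_azimuth(da, a_groove), 0.0)  # A's groove faces B
        if tmpl == "groove_backbone_major":
            _roll_to(db, _backbone_azimuth(db), 180.0)   # B's backbone into A
        elif tmpl == "groove_groove_major":
            _roll_to(db, _groove_azimuth(db, "major"), 180.0)
        else:
            _roll_to(db, _groove_azimuth(db, "minor"), 180.0)

    alpha = np.deg2rad(spec.alpha_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    db.transform(Rx, np.array([spec.interaxial_distance, 0.0, 0.0]))

    out = BuiltCrossover(duplex_a=da, duplex_b=db, spec=spec)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for a in out.atoms():
            a.position = a.position + rng.normal(0.0, noise_sigma, 3)
    return out


def _groove_azimuth(built: BuiltDuplex, groove: str) -> float:
    """Azimuth (deg, about +z) of the requested groove at the duplex centre,
    from the detected mid-pair frame."""
    dup = built.to_duplex()
    mid = len(dup.pairs) // 2
    x = dup.pairs[mid].x_axis
    az = np.degrees(np.arctan2(x[1], x[0]))
    return az if groove == "major" else az + 180.0


def _backbone_azimuth(built: BuiltDuplex) -> float:
    """Azimuth of the strand-I phosphate nearest the duplex centre."""
    chain_i = built.chains()[built.chain_ids[0]]
    ps = [a for a in chain_i if a.name == "P"]
    p = min(ps, key=lambda a: abs(a.position[2]))
    return float(np.degrees(np.arctan2(p.position[1], p.position[0])))


def _roll_to(built: BuiltDuplex, current_az_deg: float, target_az_deg: float) -> None:
    """Roll the duplex about its own (+z) axis so ``current`` lands on
    ``target``."""
    g = np.deg2rad(target_az_deg - current_az_deg)
    Rz = np.array([
        [np.cos(g), -np.sin(g), 0.0],
        [np.sin(g), np.cos(g), 0.0],
        [0.0, 0.0, 1.0],
    ])
    built.transform(Rz, np.zeros(3))


def make_mock_crystal(
    built,
    cell: UnitCell,
    path,
    operators=None,
) -> CrystalModel:
    """Write a designed assembly as a mock crystal (PDB with CRYST1).

    ``built`` is a :class:`BuiltDuplex`, :class:`BuiltCrossover`, or a plain
    atom list; operators default to the internal table entry for the cell's
    space group.
    """
    if isinstance(built, BuiltCrossover):
        atoms = built.atoms()
    elif isinstance(built, BuiltDuplex):
        atoms = built.atoms
    else:
        atoms = list(built)
    span = np.ptp(np.array([a.position for a in atoms]), axis=0)
    if np.any(span > np.array([cell.a, cell.b, cell.c]) * 3):
        raise ValueError("assembly much larger than the unit cell")
    ops = operators if operators is not None else operators_for(cell.space_group)
    model = CrystalModel(atoms=[a.moved(a.position) for a in atoms], cell=cell, operators=ops)
    _io.write_structure(model, path)
    return model


def add_ion(
    atoms: list[AtomRecord], position, element: str = "Mg", chain_id: str = "Z",
    residue_number: int = 1,
) -> AtomRecord:
    """Append a monoatomic cation record (fixture helper)."""
    serial = max((a.serial for a in atoms), default=0) + 1
    ion = AtomRecord(
        serial=serial, name=element.upper(), element=element,
        residue_name=element.upper(), chain_id=chain_id,
        residue_number=residue_number, position=np.asarray(position, dtype=float),
        is_hetero=True,
    )
    atoms.append(ion)
    return ion
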