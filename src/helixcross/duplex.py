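"""Watson-Crick base-pair detection, base-pair reference frames, and best
linear helical axes of B-DNA duplexes.

The reference frame of a pair follows the standard convention: x points into
the major groove, y along the C1'-C1' direction toward strand I, z completes
the right-handed triad and runs along the strand-I 5'→3' helix progression.
The duplex axis is the total-least-squares line through the pair origins
(C1' midpoints); on a straight duplex the fit rmsd is zero, and a large rmsd
flags curvature (e.g. nucleosomal DNA) where a single straight axis is
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AtomRecord,
    NUCLEOTIDE_LETTERS,
    PURINE_LETTERS,
)

# Geometric Watson-Crick criteria (conventional values, exercised on fixtures)
WC_N1_N3_MAX = 3.5       # Å, purine N1 – pyrimidine N3
WC_NORMAL_MAX_DEG = 65.0  # max angle between base-plane normals
WC_C1_C1_RANGE = (9.0, 11.5)  # Å
CURVATURE_RMSD = 2.0     # Å, axis-fit rmsd above which a duplex counts as bent

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A", "I": "C"}
_WC_PAIRS = {("A", "T"), ("A", "U"), ("G", "C"), ("I", "C")}
_WOBBLE_PAIRS = {("G", "T"), ("G", "U"), ("I", "T"), ("I", "U")}

PURINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]

# Groove-edge atoms used to orient the frame x-axis.
MAJOR_EDGE = {
    "purine": ["N7", "O6", "N6", "C5"],
    "pyrimidine": ["C5", "N4", "O4"],
}
MINOR_EDGE = {"purine": ["N3", "N2"], "pyrimidine": ["O2"]}


class FrameError(ValueError):
    """A base-pair frame could not be built (missing ring atoms)."""


@dataclass
class Nucleotide:
    """One nucleotide residue: atom lookup plus base classification."""

    chain_id: str
    number: int
    residue_name: str
    letter: str
    atoms: dict[str, AtomRecord]

    @property
    def is_purine(self) -> bool:
        return self.letter in PURINE_LETTERS

    @property
    def kind(self) -> str:
        return "purine" if self.is_purine else "pyrimidine"

    def pos(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name].position
        except KeyError:
            raise FrameError(
                f"residue {self.chain_id}{self.number} ({self.residue_name}) "
                f"lacks atom {name}"
            ) from None

    def ring_coords(self) -> np.ndarray:
        ring = PURINE_RING if self.is_purine else PYRIMIDINE_RING
        pts = [self.atoms[n].position for n in ring if n in self.atoms]
        if len(pts) < 4:
            raise FrameError(
                f"residue {self.chain_id}{self.number} has incomplete base ring"
            )
        return np.array(pts)

    def base_normal(self) -> np.ndarray:
        pts = self.ring_coords()
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts)
        return vt[2]

    @property
    def glycosidic_n(self) -> str:
        return "N9" if self.is_purine else "N1"

    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.number}"


def group_nucleotides(atoms: Sequence[AtomRecord]) -> list[Nucleotide]:
    """Split a chain's atoms into nucleotide residues (file order)."""
    by_res: dict[tuple, list[AtomRecord]] = {}
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.insertion_code)
        by_res.setdefault(key, []).append(atom)
    residues = []
    for (chain_id, number, _), res_atoms in by_res.items():
        names = {a.name.replace("*", "'") for a in res_atoms}
        if "C1'" not in names:
            continue
        res_name = res_atoms[0].residue_name.strip().upper()
        letter = NUCLEOTIDE_LETTERS.get(res_name)
        if letter is None:
            # modified base not in the table: classify by glycosidic nitrogen
            letter = "G" if "N9" in names else ("C" if "N1" in names else None)
            if letter is None:
                continue
        residues.append(
            Nucleotide(
                chain_id=chain_id,
                number=number,
                residue_name=res_name,
                letter=letter,
                atoms={a.name.replace("*", "'"): a for a in res_atoms},
            )
        )
    return residues


@dataclass
class BasePair:
    """A base pair with its reference frame (frame fields set by
    :func:`base_pair_frame`)."""

    residue_i: Nucleotide   # strand I
    residue_j: Nucleotide   # strand II
    pair_type: str = "noncanonical"
    origin: Optional[np.ndarray] = None
    x_axis: Optional[np.ndarray] = None
    y_axis: Optional[np.ndarray] = None
    z_axis: Optional[np.ndarray] = None


@dataclass
class Duplex:
    """An ordered run of base pairs (strand I 5'→3').

    ``residues_i``/``residues_ii`` hold *all* nucleotides of the two strands
    (each ordered by residue number), including any whose pair fell below the
    detection thresholds: the sugar-phosphate backbone exists — and makes
    contacts — whether or not the base pair was called.
    """

    pairs: list[BasePair]
    sequence_i: str
    sequence_ii: str
    source: tuple = ("", "")
    residues_i: list[Nucleotide] = field(default_factory=list)
    residues_ii: list[Nucleotide] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues_i:
            self.residues_i = [p.residue_i for p in self.pairs]
        if not self.residues_ii:
            self.residues_ii = [p.residue_j for p in self.pairs[::-1]]

    def __len__(self) -> int:
        return len(self.pairs)

    def origins(self) -> np.ndarray:
        return np.array([p.origin for p in self.pairs])

    def all_residues(self) -> list[Nucleotide]:
        return list(self.residues_i) + list(self.residues_ii)

    def atoms(self) -> list[AtomRecord]:
        out = []
        for res in self.all_residues():
            out.extend(res.atoms.values())
        return out

    def phosphorus_atoms(self) -> list[tuple[Nucleotide, AtomRecord]]:
        return [
            (res, res.atoms["P"])
            for res in self.all_residues()
            if "P" in res.atoms
        ]


@dataclass
class HelicalAxisFit:
    """Best linear axis of a duplex: point + unit direction + fit quality.

    ``seg_min``/``seg_max`` bound the fitted segment (projections of the pair
    origins onto the axis, relative to ``point``)."""

    point: np.ndarray
    direction: np.ndarray
    rmsd: float
    curvature_flag: bool
    seg_min: float = 0.0
    seg_max: float = 0.0

    def at(self, t: float) -> np.ndarray:
        return self.point + t * self.direction

    @property
    def length(self) -> float:
        return self.seg_max - self.seg_min


def detect_base_pairs(
    chain_a: Sequence[AtomRecord] | list[Nucleotide],
    chain_b: Sequence[AtomRecord] | list[Nucleotide],
) -> list[BasePair]:
    """Detect Watson-Crick (and wobble) pairs between two nucleic chains.

    A pair is called when purine N1 – pyrimidine N3 ≤ 3.5 Å, the base-plane
    normals agree within 65°, and the C1'-C1' distance lies in [9.0, 11.5] Å.
    Pairs are returned ordered along strand I (``chain_a``); assignment is
    greedy one-to-one by N1-N3 distance.  Modified bases pair through their
    parent-base atoms.
    """
    res_a = chain_a if (chain_a and isinstance(chain_a[0], Nucleotide)) else group_nucleotides(chain_a)
    res_b = chain_b if (chain_b and isinstance(chain_b[0], Nucleotide)) else group_nucleotides(chain_b)

    candidates = []
    for ra in res_a:
        for rb in res_b:
            pur, pyr = (ra, rb) if ra.is_purine else (rb, ra)
            if pur.is_purine == pyr.is_purine:
                continue  # need one purine + one pyrimidine
            if "N1" not in pur.atoms or "N3" not in pyr.atoms:
                continue
            d = float(np.linalg.norm(pur.pos("N1") - pyr.pos("N3")))
            if d > WC_N1_N3_MAX:
                continue
            try:
                na, nb = ra.base_normal(), rb.base_normal()
            except FrameError:
                continue
            cosang = abs(float(na @ nb))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > WC_NORMAL_MAX_DEG:
                continue
            if "C1'" not in ra.atoms or "C1'" not in rb.atoms:
                continue
            dc1 = float(np.linalg.norm(ra.pos("C1'") - rb.pos("C1'")))
            if not (WC_C1_C1_RANGE[0] <= dc1 <= WC_C1_C1_RANGE[1]):
                continue
            candidates.append((d, ra, rb))

    candidates.sort(key=lambda t: t[0])
    used_a, used_b, pairs = set(), set(), []
    for d, ra, rb in candidates:
        if id(ra) in used_a or id(rb) in used_b:
            continue
        used_a.add(id(ra))
        used_b.add(id(rb))
        pairs.append(BasePair(residue_i=ra, residue_j=rb, pair_type=_pair_type(ra, rb)))
    pairs.sort(key=lambda p: (p.residue_i.number, p.residue_i.chain_id))
    return _antiparallel_filter(pairs)


def _antiparallel_filter(pairs: list[BasePair]) -> list[BasePair]:
    """Keep the longest antiparallel register: with pairs ordered by strand-I
    residue number, strand-II numbers must be strictly decreasing.  Discards
    occasional spurious diagonal pairings that pass the distance criteria."""
    if len(pairs) < 3:
        return pairs
    n = len(pairs)
    seq = [p.residue_j.number for p in pairs]
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] > seq[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    k = int(np.argmax(best_len))
    keep = []
    while k >= 0:
        keep.append(k)
        k = prev[k]
    return [pairs[i] for i in reversed(keep)]


def _pair_type(ra: Nucleotide, rb: Nucleotide) -> str:
    key = tuple(sorted((ra.letter, rb.letter)))
    for pur, pyr in _WC_PAIRS:
        if key == tuple(sorted((pur, pyr))):
            return "WC"
    for pur, pyr in _WOBBLE_PAIRS:
        if key == tuple(sorted((pur, pyr))):
            return "wobble"
    return "noncanonical"


def base_pair_frame(pair: BasePair) -> BasePair:
    """Populate the pair's reference frame.

    origin: C1' midpoint; y: unit vector along C1'(II)→C1'(I) (toward the
    strand-I sugar); z: mean base normal signed so that x = y × z points at
    the major-groove edge atoms; axes re-orthogonalised to 1e-9.
    """
    ri, rj = pair.residue_i, pair.residue_j
    c1_i, c1_j = ri.pos("C1'"), rj.pos("C1'")
    origin = 0.5 * (c1_i + c1_j)
    y = _unit(c1_i - c1_j)

    ni, nj = ri.base_normal(), rj.base_normal()
    if ni @ nj < 0:
        nj = -nj
    n = _unit(ni + nj)
    # orthogonalise candidate z against y
    z = _unit(n - (n @ y) * y)

    major_pts = [
        ri.atoms[a].position for a in MAJOR_EDGE[ri.kind] if a in ri.atoms
    ] + [rj.atoms[a].position for a in MAJOR_EDGE[rj.kind] if a in rj.atoms]
    if not major_pts:
        raise FrameError(f"pair {ri.label()}:{rj.label()} has no major-edge atoms")
    major_dir = np.mean(major_pts, axis=0) - origin

    x = np.cross(y, z)
    if x @ major_dir < 0:
        z = -z
        x = -x
    pair.origin = origin
    pair.x_axis = _unit(x)
    pair.y_axis = y
    pair.z_axis = z
    return pair


def build_duplex(
    chain_a: Sequence[AtomRecord],
    chain_b: Sequence[AtomRecord],
    source: tuple = ("", ""),
    min_pairs: int = 4,
) -> Optional[Duplex]:
    """Assemble a duplex from two chains; ``None`` if fewer than ``min_pairs``
    pairs are found."""
    res_a = group_nucleotides(chain_a)
    res_b = group_nucleotides(chain_b)
    pairs = detect_base_pairs(res_a, res_b)
    if len(pairs) < min_pairs:
        return None
    for pair in pairs:
        base_pair_frame(pair)
    return _assemble(pairs, res_a, res_b, source)


def _assemble(pairs, res_a, res_b, source) -> Duplex:
    res_a = sorted(res_a, key=lambda r: r.number)
    res_b = sorted(res_b, key=lambda r: r.number)
    return Duplex(
        pairs=pairs,
        sequence_i="".join(r.letter for r in res_a),
        sequence_ii="".join(r.letter for r in res_b),
        source=source,
        residues_i=res_a,
        residues_ii=res_b,
    )


def fit_linear_axis(
    duplex_or_origins, window: Optional[tuple[int, int]] = None
) -> HelicalAxisFit:
    """Total-least-squares line through the base-pair origins.

    The direction is the first principal axis of the centred origin cloud,
    signed toward increasing pair index.  ``window`` restricts the fit to the
    half-open pair-index range [i, j) for contact-local axes of long, bent
    duplexes.
    """
    if isinstance(duplex_or_origins, Duplex):
        origins = duplex_or_origins.origins()
    else:
        origins = np.asarray(duplex_or_origins, dtype=float)
    if window is not None:
        origins = origins[window[0]:window[1]]
    if len(origins) < 2:
        raise ValueError("need at least two base-pair origins to fit an axis")
    center = origins.mean(axis=0)
    centered = origins - center
    if np.allclose(centered, 0.0, atol=1e-12):
        raise ValueError("degenerate origin cloud: all pair origins coincide")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    # sign toward increasing pair index
    if direction @ (origins[-1] - origins[0]) < 0:
        direction = -direction
    t = centered @ direction
    residuals = centered - np.outer(t, direction)
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return HelicalAxisFit(
        point=center,
        direction=direction,
        rmsd=rmsd,
        curvature_flag=rmsd > CURVATURE_RMSD,
        seg_min=float(t.min()),
        seg_max=float(t.max()),
    )


def find_duplexes(
    chains: list[tuple[tuple, list[AtomRecord]]],
    min_pairs: int = 4,
    prescreen: float = 30.0,
) -> list[Duplex]:
    """Pair up pooled chains into duplexes.

    ``chains`` is a list of ``(key, atoms)`` where ``key`` is a hashable
    provenance (e.g. ``(copy_label, chain_id)``).  Every unordered chain pair
    whose bounding spheres approach within ``prescreen`` Å is tested; chains
    already consumed by a better pairing are skipped (a chain belongs to at
    most one duplex, preferring the pairing with the most base pairs).
    """
    nucs = [(key, group_nucleotides(atoms)) for key, atoms in chains]
    nucs = [(k, r) for k, r in nucs if r]
    centers, radii = [], []
    for _, residues in nucs:
        pts = np.array([a.position for r in residues for a in r.atoms.values()])
        centers.append(pts.mean(axis=0))
        radii.append(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())

    candidates = []
    for i in range(len(nucs)):
        for j in range(i + 1, len(nucs)):
            gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
            if gap > prescreen:
                continue
            key_i, key_j = nucs[i][0], nucs[j][0]
            a, b = (i, j) if key_i <= key_j else (j, i)
            pairs = detect_base_pairs(nucs[a][1], nucs[b][1])
            if len(pairs) >= min_pairs:
                candidates.append((len(pairs), a, b, pairs))

    candidates.sort(key=lambda t: (-t[0], nucs[t[1]][0], nucs[t[2]][0]))
    used, duplexes = set(), []
    for _, a, b, pairs in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        for pair in pairs:
            base_pair_frame(pair)
        duplexes.append(
            _assemble(pairs, nucs[a][1], nucs[b][1], (nucs[a][0], nucs[b][0]))
        )
    return duplexes


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n
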