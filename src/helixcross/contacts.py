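"""Interaction-mode classification of crossovers, anchor contacts and cation
bridges.

Right-handed crossovers in crystals are typically *self-fitted*: the
sugar-phosphate backbone of one duplex lies inside a groove of the other,
with the penetrating phosphate hydrogen-bonded to the N4 amino groups of
nearby cytosines (major groove) or the N2 amino groups of guanines (minor
groove), often together with bridging divalent cations.  Left-handed
crossovers juxtapose grooves without backbone insertion.  This module
recovers that taxonomy from coordinates alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import AtomRecord, cation_charge_class
from .crossover import Crossover
from .duplex import Duplex, HelicalAxisFit, Nucleotide, fit_linear_axis

PENETRATION_RADIUS = 10.5   # Å: phosphate closer than this to the partner
                            # axis counts as inserted (B-DNA P radius ≈ 9-10)
HBOND_CUTOFF = 3.4          # Å donor–acceptor (heavy atoms)
PROXIMAL_WINDOW = (3.5, 4.5)  # Å, "close but not bonded" anchor window
BRIDGE_CUTOFF = 4.0         # Å ion–DNA contact (allows unmodelled waters)
SECTOR_HALF_WIDTH = 60.0    # deg: |θ| ≤ 60 major, |θ| ≥ 120 minor
RISE = 3.4                  # Å, end-overhang allowance for groove sectors

PHOSPHATE_OXYGENS = ("OP1", "OP2", "O1P", "O2P", "O5'", "O3'")


class ContactMode(enum.Enum):
    MAJOR_GROOVE_BACKBONE = "Major-groove/backbone"
    MINOR_GROOVE_BACKBONE = "Minor-groove/backbone"
    MAJOR_MAJOR = "Major <> Major"
    MINOR_MINOR = "Minor <> Minor"
    MAJOR_MINOR = "Major <> Minor"
    UNCLASSIFIED = "Unclassified"

    @property
    def is_groove_backbone(self) -> bool:
        return self in (
            ContactMode.MAJOR_GROOVE_BACKBONE,
            ContactMode.MINOR_GROOVE_BACKBONE,
        )

    @property
    def is_groove_groove(self) -> bool:
        return self in (
            ContactMode.MAJOR_MAJOR,
            ContactMode.MINOR_MINOR,
            ContactMode.MAJOR_MINOR,
        )


@dataclass
class GrooveSector:
    sector: str          # "major" | "minor" | "backbone_side"
    radial_distance: float
    theta_deg: float
    pair_index: int
    out_of_range: bool = False


@dataclass
class PenetratingPhosphate:
    residue: Nucleotide          # phosphate owner (penetrating duplex)
    atom: AtomRecord             # the P atom
    groove: str                  # groove of the *penetrated* duplex
    radial_distance: float
    host: str                    # "a" or "b": which duplex is penetrated


@dataclass
class AnchorContact:
    """A cytosine-N4 (or guanine-N2) to phosphate anchor.

    ``hbond_anchor``: donor-oxygen distance ≤ 3.4 Å; ``proximal_anchor``:
    distance in [3.5, 4.5] Å.  The gap (3.4, 3.5) is a deliberate no-man's
    land keeping the two categories disjoint.  Minor-groove anchors through
    guanine N2 are kinded ``guanine_minor_anchor``.
    """

    kind: str
    base: Nucleotide
    donor_atom: str
    phosphate_residue: Nucleotide
    phosphate_atom: str
    distance: float


@dataclass
class CationBridge:
    ion: AtomRecord
    partner_a_atoms: list[AtomRecord]
    partner_b_atoms: list[AtomRecord]
    max_contact_distance: float
    charge_class: str = "divalent"


@dataclass
class ContactReport:
    crossover: Crossover
    mode: ContactMode
    penetrating_phosphates: list[PenetratingPhosphate] = field(default_factory=list)
    anchors: list[AnchorContact] = field(default_factory=list)
    bridges: list[CationBridge] = field(default_factory=list)
    facing: tuple[str, str] = ("", "")


def groove_sector(
    point: np.ndarray, duplex: Duplex, axis: Optional[HelicalAxisFit] = None
) -> GrooveSector:
    """Which groove sector of ``duplex`` a point falls in.

    The nearest base-pair frame (by axial projection) defines the local
    reference: θ is the in-plane angle between the point and the frame +x
    (major-groove direction).  |θ| ≤ 60° → major; |θ| ≥ 120° → minor; the
    two flanks are backbone_side.  The radial distance is measured from the
    fitted axis.
    """
    if axis is None:
        axis = fit_linear_axis(duplex)
    point = np.asarray(point, dtype=float)
    t = float((point - axis.point) @ axis.direction)
    out_of_range = t < axis.seg_min - RISE or t > axis.seg_max + RISE
    radial = float(
        np.linalg.norm((point - axis.point) - t * axis.direction)
    )
    origins = duplex.origins()
    proj = (origins - axis.point) @ axis.direction
    k = int(np.argmin(np.abs(proj - t)))
    pair = duplex.pairs[k]
    x_ref, y_ref = _twist_corrected_axes(duplex, axis, proj, k, t)
    v = point - pair.origin
    theta = float(np.degrees(np.arctan2(v @ y_ref, v @ x_ref)))
    if abs(theta) <= SECTOR_HALF_WIDTH:
        sector = "major"
    elif abs(theta) >= 180.0 - SECTOR_HALF_WIDTH:
        sector = "minor"
    else:
        sector = "backbone_side"
    return GrooveSector(
        sector=sector,
        radial_distance=radial,
        theta_deg=theta,
        pair_index=k,
        out_of_range=out_of_range,
    )


def _twist_corrected_axes(duplex, axis, proj, k, t):
    """Frame x/y of pair ``k`` unwound by the local helical twist to the
    axial position ``t`` of the query point.

    The groove direction rotates with the helix (~36° per pair step), so when
    the query point projects between pairs — or next to a pair that failed
    detection — the nearest raw frame can be off by tens of degrees.  The
    local twist rate is estimated from the neighbouring frame and the frame
    axes are rotated about the fitted axis by rate × offset.
    """
    pair = duplex.pairs[k]
    d = axis.direction
    x0 = _project_unit(pair.x_axis, d)
    y0 = np.cross(d, x0)
    delta = t - proj[k]
    m = k + 1 if k + 1 < len(duplex.pairs) else k - 1
    if m < 0 or abs(proj[m] - proj[k]) < 1e-6:
        return x0, y0
    xm = _project_unit(duplex.pairs[m].x_axis, d)
    step = float(np.degrees(np.arctan2(np.cross(x0, xm) @ d, x0 @ xm)))
    rate = step / (proj[m] - proj[k])   # deg per Å along the axis
    gamma = np.deg2rad(rate * delta)
    x_ref = np.cos(gamma) * x0 + np.sin(gamma) * y0
    y_ref = np.cross(d, x_ref)
    return x_ref, y_ref


def _project_unit(v, d):
    w = v - (v @ d) * d
    n = np.linalg.norm(w)
    return w / n if n > 1e-9 else v


def classify_mode(
    crossover: Crossover, penetration_radius: float = PENETRATION_RADIUS
) -> ContactReport:
    """Classify the interaction mode of a crossover.

    A phosphorus atom of one duplex "penetrates" the partner when its groove
    sector there is major (or minor) with radial distance ≤ the penetration
    radius.  Any major-penetration → Major-groove/backbone; else any
    minor-penetration → Minor-groove/backbone; otherwise the grooves facing
    the partner across the closest-approach vector decide the groove-groove
    mode.
    """
    pens: list[PenetratingPhosphate] = []
    for host, host_dx, host_axis, guest_dx in (
        ("b", crossover.duplex_b, crossover.axis_b, crossover.duplex_a),
        ("a", crossover.duplex_a, crossover.axis_a, crossover.duplex_b),
    ):
        for res, p_atom in guest_dx.phosphorus_atoms():
            sec = groove_sector(p_atom.position, host_dx, host_axis)
            if sec.out_of_range or sec.sector == "backbone_side":
                continue
            if sec.radial_distance <= penetration_radius:
                pens.append(
                    PenetratingPhosphate(
                        residue=res,
                        atom=p_atom,
                        groove=sec.sector,
                        radial_distance=sec.radial_distance,
                        host=host,
                    )
                )
    facing_a = groove_sector(
        crossover.point_b, crossover.duplex_a, crossover.axis_a
    ).sector
    facing_b = groove_sector(
        crossover.point_a, crossover.duplex_b, crossover.axis_b
    ).sector

    if any(p.groove == "major" for p in pens):
        mode = ContactMode.MAJOR_GROOVE_BACKBONE
        pens = [p for p in pens if p.groove == "major"]
    elif any(p.groove == "minor" for p in pens):
        mode = ContactMode.MINOR_GROOVE_BACKBONE
    elif facing_a == "major" and facing_b == "major":
        mode = ContactMode.MAJOR_MAJOR
    elif facing_a == "minor" and facing_b == "minor":
        mode = ContactMode.MINOR_MINOR
    elif {facing_a, facing_b} == {"major", "minor"}:
        mode = ContactMode.MAJOR_MINOR
    else:
        mode = ContactMode.UNCLASSIFIED
    return ContactReport(
        crossover=crossover,
        mode=mode,
        penetrating_phosphates=pens,
        facing=(facing_a, facing_b),
    )


def detect_anchor_contacts(
    report: ContactReport,
    hbond_cutoff: float = HBOND_CUTOFF,
    proximal_window: tuple[float, float] = PROXIMAL_WINDOW,
) -> ContactReport:
    """Fill in the sequence-specific anchors of groove-backbone crossovers.

    For every penetrating phosphate, amino-group donors of the penetrated
    duplex — cytosine N4 for major-groove insertion, guanine N2 for
    minor-groove insertion — are measured to the phosphate oxygens.  Distance
    ≤ 3.4 Å → hydrogen-bond anchor; within [3.5, 4.5] Å → proximal anchor.
    Groove-groove modes have no sequence-specific anchors by construction.
    """
    report.anchors = []
    if not report.mode.is_groove_backbone:
        return report
    best: dict[int, AnchorContact] = {}
    for pen in report.penetrating_phosphates:
        host_dx = (
            report.crossover.duplex_a if pen.host == "a" else report.crossover.duplex_b
        )
        if pen.groove == "major":
            donors = [
                (res, "N4") for res in host_dx.all_residues()
                if res.letter == "C" and "N4" in res.atoms
            ]
        else:
            donors = [
                (res, "N2") for res in host_dx.all_residues()
                if res.letter == "G" and "N2" in res.atoms
            ]
        for res, donor_name in donors:
            dpos = res.pos(donor_name)
            dists = [
                (float(np.linalg.norm(dpos - pen.residue.atoms[ox].position)), ox)
                for ox in PHOSPHATE_OXYGENS
                if ox in pen.residue.atoms
            ]
            if not dists:
                continue
            dist, ox = min(dists)
            if dist <= hbond_cutoff:
                kind = "hbond_anchor" if donor_name == "N4" else "guanine_minor_anchor"
            elif proximal_window[0] <= dist <= proximal_window[1]:
                kind = (
                    "proximal_anchor" if donor_name == "N4" else "guanine_minor_anchor"
                )
            else:
                continue
            contact = AnchorContact(
                kind=kind,
                base=res,
                donor_atom=donor_name,
                phosphate_residue=pen.residue,
                phosphate_atom=ox,
                distance=dist,
            )
            prev = best.get(id(res))
            if prev is None or dist < prev.distance:
                best[id(res)] = contact
    report.anchors = sorted(best.values(), key=lambda a: a.distance)
    return report


def detect_cation_bridges(
    report: ContactReport,
    ions: list[AtomRecord],
    cutoff: float = BRIDGE_CUTOFF,
) -> ContactReport:
    """Find cations simultaneously contacting both duplexes of the crossover.

    An ion bridges when it has at least one DNA atom of each duplex within
    the cutoff (4.0 Å by default, covering inner-sphere and tight
    water-mediated geometries with unmodelled waters).  Monovalent ions are
    reported but flagged non-divalent.
    """
    report.bridges = []
    coords_a = np.array([a.position for a in report.crossover.duplex_a.atoms()])
    coords_b = np.array([a.position for a in report.crossover.duplex_b.atoms()])
    atoms_a = report.crossover.duplex_a.atoms()
    atoms_b = report.crossover.duplex_b.atoms()
    for ion in ions:
        da = np.linalg.norm(coords_a - ion.position, axis=1)
        db = np.linalg.norm(coords_b - ion.position, axis=1)
        hits_a = [atoms_a[k] for k in np.nonzero(da <= cutoff)[0]]
        hits_b = [atoms_b[k] for k in np.nonzero(db <= cutoff)[0]]
        if hits_a and hits_b:
            dmax = max(da[da <= cutoff].max(), db[db <= cutoff].max())
            report.bridges.append(
                CationBridge(
                    ion=ion,
                    partner_a_atoms=hits_a,
                    partner_b_atoms=hits_b,
                    max_contact_distance=float(dmax),
                    charge_class=cation_charge_class(ion),
                )
            )
    return report
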