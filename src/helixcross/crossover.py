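"""Juxtaposed duplex pairs and their signed (chiral) crossing angle.

Sign convention
---------------
Let u, v be the two axis directions re-signed so that u·v ≥ 0 (the crossing
angle is always reported as the acute angle), and let c run from the closest
point on axis a to the closest point on axis b.  Then

    alpha = sign((u × v) · c) * arccos(u·v)   in (-90°, +90°]

A positive alpha is a right-handed crossover: closing the small angle between
the projected axes requires a clockwise rotation when viewed from the front
helix.  This matches the physics of supercoiling — segment pairs in the
interwound superhelix of overwound (positively supercoiled) DNA give
alpha > 0 with this convention, underwound DNA gives alpha < 0 — and is
verified in the tests both by a Gauss-linking construction of an explicit
plectoneme and by the groove-backbone fixture (the backbone of one duplex
tracks the major groove of the other only in right-handed geometry).
Exact-90° crossings are reported as +90 (fold-boundary tie convention).

The sign flips under mirror reflection (the triple product is a pseudoscalar)
and is invariant under proper rigid motions and under exchanging the two
duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .duplex import Duplex, HelicalAxisFit, fit_linear_axis

DEFAULT_MAX_INTERAXIAL = 22.0  # Å
DEFAULT_MIN_OVERLAP = 3.4      # Å, one helical rise
LOCAL_WINDOW = 12              # pairs; contact-local axis window for bent DNA

_PARALLEL_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when the crossing-angle sign is undefined (coincident axes or
    zero inter-axial separation)."""


@dataclass
class Crossover:
    """A juxtaposed duplex pair with signed crossing angle and approach
    geometry."""

    duplex_a: Duplex
    duplex_b: Duplex
    axis_a: HelicalAxisFit
    axis_b: HelicalAxisFit
    point_a: np.ndarray
    point_b: np.ndarray
    interaxial_distance: float
    alpha_deg: float
    parallel: bool = False
    low_confidence: bool = False

    @property
    def handedness(self) -> str:
        return "right" if self.alpha_deg > 0 else "left"

    @property
    def closest_points(self):
        return self.point_a, self.point_b


def closest_approach(
    axis_a: HelicalAxisFit, axis_b: HelicalAxisFit
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Minimum-distance points between the two fitted axis segments.

    Returns ``(point_a, point_b, distance, parallel)``.  For parallel axes
    the midpoint of the overlapping parameter range is used (flagged).
    """
    p0 = axis_a.at(axis_a.seg_min)
    d1 = axis_a.direction * (axis_a.seg_max - axis_a.seg_min)
    q0 = axis_b.at(axis_b.seg_min)
    d2 = axis_b.direction * (axis_b.seg_max - axis_b.seg_min)
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    if a < 1e-20 or e < 1e-20:
        raise ValueError("zero-length axis segment")
    r = p0 - q0
    b = float(d1 @ d2)
    c = float(d1 @ r)
    f = float(d2 @ r)
    denom = a * e - b * b
    parallel = denom <= _PARALLEL_TOL * a * e
    if parallel:
        # overlap-midpoint convention: project segment b onto a
        t0 = -c / a
        t1 = (b - c) / a
        lo, hi = min(t0, t1), max(t0, t1)
        s = 0.5 * (max(0.0, lo) + min(1.0, hi))
        s = min(1.0, max(0.0, s))
        t = (b * s + f) / e
        t = min(1.0, max(0.0, t))
    else:
        s = (b * f - c * e) / denom
        s = min(1.0, max(0.0, s))
        t = (b * s + f) / e
        if t < 0.0 or t > 1.0:
            t = min(1.0, max(0.0, t))
            s = min(1.0, max(0.0, (b * t - c) / a))
    pa = p0 + s * d1
    pb = q0 + t * d2
    dist = float(np.linalg.norm(pa - pb))
    return pa, pb, dist, parallel


def signed_crossing_angle(
    axis_a: HelicalAxisFit,
    axis_b: HelicalAxisFit,
    closest_points: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Signed acute crossing angle in degrees, in (-90, +90].

    Raises :class:`DegenerateGeometryError` when the sign is undefined
    (coincident axes, or zero inter-axial distance).
    """
    if closest_points is None:
        pa, pb, dist, parallel = closest_approach(axis_a, axis_b)
    else:
        pa, pb = closest_points
        dist = float(np.linalg.norm(np.asarray(pb) - np.asarray(pa)))
    u = axis_a.direction / np.linalg.norm(axis_a.direction)
    v = axis_b.direction / np.linalg.norm(axis_b.direction)
    if u @ v < 0:
        v = -v
    dot = float(np.clip(u @ v, -1.0, 1.0))
    magnitude = float(np.degrees(np.arccos(dot)))
    n = np.cross(u, v)
    if np.linalg.norm(n) < _PARALLEL_TOL:
        if dist < 1e-9:
            raise DegenerateGeometryError("coincident axes: angle sign undefined")
        return 0.0
    if dist < 1e-9:
        raise DegenerateGeometryError(
            "intersecting axes (zero inter-axial distance): sign undefined"
        )
    if magnitude >= 90.0 - 1e-9:
        return 90.0  # fold-boundary tie: report +90
    c = np.asarray(pb) - np.asarray(pa)
    sign = float(np.sign(n @ c))
    if sign == 0.0:
        raise DegenerateGeometryError("closest-approach vector in axis plane")
    return sign * magnitude


def find_crossovers(
    duplexes: list[Duplex],
    max_distance: float = DEFAULT_MAX_INTERAXIAL,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    window: int = LOCAL_WINDOW,
    dedup: bool = True,
    require_keys: Optional[set] = None,
) -> list[Crossover]:
    """All juxtaposed duplex pairs within ``max_distance`` whose closest
    points lie interior to both fitted segments by at least ``min_overlap``.

    Symmetry-equivalent crossovers are collapsed to one representative
    (lexicographically smallest provenance).  ``require_keys`` restricts to
    crossovers touching at least one duplex whose source intersects the given
    provenance keys (used to anchor lattice crossovers to the asymmetric
    unit).
    """
    fits = [_contact_axis(d, window) for d in duplexes]
    out: list[Crossover] = []
    for i in range(len(duplexes)):
        for j in range(i + 1, len(duplexes)):
            da, db = duplexes[i], duplexes[j]
            if set(da.source) & set(db.source):
                continue  # shares a chain instance: not a physical crossover
            if require_keys is not None and not (
                (set(da.source) & require_keys) or (set(db.source) & require_keys)
            ):
                continue
            fa, fb = fits[i], fits[j]
            if da.source > db.source:
                da, db, fa, fb = db, da, fb, fa
            pa, pb, dist, parallel = closest_approach(fa, fb)
            if dist > max_distance:
                continue
            if parallel and dist < 1e-6:
                continue  # coincident image of the same duplex
            if len(da.pairs) > window or len(db.pairs) > window:
                fa, fb, pa, pb, dist, parallel = _refine_local(
                    da, db, fa, fb, pa, pb, window
                )
                if dist > max_distance:
                    continue
            if not (_interior(fa, pa, min_overlap) and _interior(fb, pb, min_overlap)):
                continue
            try:
                alpha = signed_crossing_angle(fa, fb, (pa, pb))
            except DegenerateGeometryError:
                continue
            out.append(
                Crossover(
                    duplex_a=da,
                    duplex_b=db,
                    axis_a=fa,
                    axis_b=fb,
                    point_a=pa,
                    point_b=pb,
                    interaxial_distance=dist,
                    alpha_deg=alpha,
                    parallel=parallel,
                    low_confidence=fa.curvature_flag or fb.curvature_flag,
                )
            )
    out.sort(key=lambda x: (x.duplex_a.source, x.duplex_b.source))
    if dedup:
        out = _dedup(out)
    return out


def _contact_axis(duplex: Duplex, window: int) -> HelicalAxisFit:
    return fit_linear_axis(duplex)


def _refine_local(da, db, fa, fb, pa, pb, window):
    """Contact-local axis windows for long (bent) duplexes, iterated twice."""
    for _ in range(2):
        fa = _window_fit(da, fa, pa, window)
        fb = _window_fit(db, fb, pb, window)
        pa, pb, dist, parallel = closest_approach(fa, fb)
    return fa, fb, pa, pb, dist, parallel


def _window_fit(duplex, fit, near_point, window):
    if len(duplex.pairs) <= window:
        return fit
    origins = duplex.origins()
    k = int(np.argmin(np.linalg.norm(origins - near_point, axis=1)))
    lo = max(0, min(k - window // 2, len(origins) - window))
    return fit_linear_axis(origins[lo:lo + window])


def _interior(fit: HelicalAxisFit, point: np.ndarray, margin: float) -> bool:
    t = float((point - fit.point) @ fit.direction)
    return (t >= fit.seg_min + margin) and (t <= fit.seg_max - margin)


def _dedup(crossovers: list[Crossover]) -> list[Crossover]:
    seen = {}
    for xo in crossovers:
        key = (
            round(xo.alpha_deg, 2),
            round(xo.interaxial_distance, 2),
            tuple(sorted((xo.duplex_a.sequence_i, xo.duplex_b.sequence_i))),
        )
        if key not in seen:
            seen[key] = xo
    return list(seen.values())
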