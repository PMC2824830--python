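"""Space-group operator table and xyz-triplet parsing.

Coordinate files do not always carry their symmetry operators (PDB format
never does), so a small internal table supplies the general positions for the
space groups that occur in B-DNA packing analyses, keyed by Hermann-Mauguin
symbol.  Operators are stored in the standard "xyz triplet" notation, e.g.
``-y,x-y,z+1/3``.  Rhombohedral groups are given in the hexagonal setting
(identical to their ``H``-symbol aliases), matching deposited coordinates.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .model import SymmetryOperator

_AXES = "xyz"

# General positions per space group.  Centred groups list the centring
# translations explicitly so every entry is a plain operator list.
_TABLE: dict[str, list[str]] = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "C121": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P212121": [
        "x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z",
    ],
    "C2221": [
        "x,y,z", "-x,-y,z+1/2", "-x,y,-z+1/2", "x,-y,-z",
        "x+1/2,y+1/2,z", "-x+1/2,-y+1/2,z+1/2", "-x+1/2,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z",
    ],
    "I222": [
        "x,y,z", "-x,-y,z", "x,-y,-z", "-x,y,-z",
        "x+1/2,y+1/2,z+1/2", "-x+1/2,-y+1/2,z+1/2",
        "x+1/2,-y+1/2,-z+1/2", "-x+1/2,y+1/2,-z+1/2",
    ],
    "P41": ["x,y,z", "-x,-y,z+1/2", "-y,x,z+1/4", "y,-x,z+3/4"],
    "P43": ["x,y,z", "-x,-y,z+1/2", "-y,x,z+3/4", "y,-x,z+1/4"],
    "P4122": [
        "x,y,z", "-x,-y,z+1/2", "-y,x,z+1/4", "y,-x,z+3/4",
        "-x,y,-z", "x,-y,-z+1/2", "y,x,-z+3/4", "-y,-x,-z+1/4",
    ],
    "P4322": [
        "x,y,z", "-x,-y,z+1/2", "-y,x,z+3/4", "y,-x,z+1/4",
        "-x,y,-z", "x,-y,-z+1/2", "y,x,-z+1/4", "-y,-x,-z+3/4",
    ],
    "P31": ["x,y,z", "-y,x-y,z+1/3", "-x+y,-x,z+2/3"],
    "P32": ["x,y,z", "-y,x-y,z+2/3", "-x+y,-x,z+1/3"],
    "R3": [
        "x,y,z", "-y,x-y,z", "-x+y,-x,z",
        "x+2/3,y+1/3,z+1/3", "-y+2/3,x-y+1/3,z+1/3", "-x+y+2/3,-x+1/3,z+1/3",
        "x+1/3,y+2/3,z+2/3", "-y+1/3,x-y+2/3,z+2/3", "-x+y+1/3,-x+2/3,z+2/3",
    ],
    "P3121": [
        "x,y,z", "-y,x-y,z+1/3", "-x+y,-x,z+2/3",
        "y,x,-z", "x-y,-y,-z+2/3", "-x,-x+y,-z+1/3",
    ],
    "P3221": [
        "x,y,z", "-y,x-y,z+2/3", "-x+y,-x,z+1/3",
        "y,x,-z", "x-y,-y,-z+1/3", "-x,-x+y,-z+2/3",
    ],
    "P61": [
        "x,y,z", "x-y,x,z+1/6", "-y,x-y,z+1/3",
        "-x,-y,z+1/2", "-x+y,-x,z+2/3", "y,-x+y,z+5/6",
    ],
    "P65": [
        "x,y,z", "x-y,x,z+5/6", "-y,x-y,z+2/3",
        "-x,-y,z+1/2", "-x+y,-x,z+1/3", "y,-x+y,z+1/6",
    ],
    "P6122": [
        "x,y,z", "x-y,x,z+1/6", "-y,x-y,z+1/3",
        "-x,-y,z+1/2", "-x+y,-x,z+2/3", "y,-x+y,z+5/6",
        "y,x,-z+1/3", "x-y,-y,-z", "-x,-x+y,-z+2/3",
        "-y,-x,-z+5/6", "-x+y,y,-z+1/2", "x,x-y,-z+1/6",
    ],
    "P6522": [
        "x,y,z", "x-y,x,z+5/6", "-y,x-y,z+2/3",
        "-x,-y,z+1/2", "-x+y,-x,z+1/3", "y,-x+y,z+1/6",
        "y,x,-z+2/3", "x-y,-y,-z", "-x,-x+y,-z+1/3",
        "-y,-x,-z+1/6", "-x+y,y,-z+1/2", "x,x-y,-z+5/6",
    ],
}

_ALIASES = {
    "H3": "R3",
    "C2": "C121",
    "P1211": "P21",
}


def normalize_symbol(symbol: str) -> str:
    """Canonicalise a Hermann-Mauguin symbol: 'P 31 2 1' -> 'P3121'."""
    key = "".join(symbol.split()).replace("_", "").upper()
    return _ALIASES.get(key, key)


def known_space_groups() -> list[str]:
    return sorted(_TABLE)


def operators_for(symbol: str) -> list[SymmetryOperator]:
    """Look up the general positions of a space group.

    Raises ``KeyError`` for symbols outside the internal table; callers fall
    back to in-file operators (mmCIF) before reaching this point.
    """
    key = normalize_symbol(symbol)
    if key not in _TABLE:
        raise KeyError(
            f"space group {symbol!r} not in internal operator table; "
            "supply a file with explicit symmetry operators"
        )
    return [parse_xyz_op(label) for label in _TABLE[key]]


def parse_xyz_op(label: str) -> SymmetryOperator:
    """Parse an xyz triplet like '-y,x-y,z+1/3' into matrices."""
    parts = label.lower().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"malformed operator string {label!r}")
    rot = np.zeros((3, 3))
    trans = np.zeros(3)
    for row, expr in enumerate(parts):
        for sign, term in _split_terms(expr):
            if term in _AXES:
                rot[row, _AXES.index(term)] += sign
            else:
                trans[row] += sign * float(Fraction(term))
    return SymmetryOperator(rotation=rot, translation=trans, label=format_xyz_op(rot, trans))


def _split_terms(expr: str):
    terms = []
    sign, token = 1, ""
    for ch in expr + "+":
        if ch in "+-":
            if token:
                terms.append((sign, token))
            sign = 1 if ch == "+" else -1
            token = ""
        else:
            token += ch
    if any(t == "" for _, t in terms) or not terms:
        raise ValueError(f"malformed operator component {expr!r}")
    return terms


def format_xyz_op(rotation: np.ndarray, translation: np.ndarray) -> str:
    """Render matrices back to canonical triplet notation."""
    out = []
    for row in range(3):
        s = ""
        for col in range(3):
            coef = rotation[row, col]
            if abs(coef) < 1e-9:
                continue
            if abs(abs(coef) - 1.0) > 1e-9:
                raise ValueError("non-unit rotation coefficient in triplet operator")
            s += ("-" if coef < 0 else ("+" if s else "")) + _AXES[col]
        frac = Fraction(translation[row]).limit_denominator(12) % 1
        if frac != 0:
            s += f"+{frac.numerator}/{frac.denominator}"
        if not s:
            raise ValueError("empty operator row")
        out.append(s)
    return ",".join(out)
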