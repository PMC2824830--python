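import numpy as np
import pytest

from helixcross.model import UnitCell
from helixcross.synthetic import (
    BuildParams,
    CrossoverSpec,
    build_crossover,
    build_ideal_bdna,
)
from helixcross.duplex import find_duplexes
from helixcross.crossover import find_crossovers


@pytest.fixture
def ideal_dodecamer():
    return build_ideal_bdna(BuildParams("ACCGGCGCCACA"))


@pytest.fixture
def gb_crossover():
    """Right-handed groove-backbone construct: B's backbone laid into A's
    major groove at +60 deg, 18 Å."""
    return build_crossover(CrossoverSpec(60.0, 18.0, "groove_backbone_major"))


@pytest.fixture
def p1_cell_100():
    return UnitCell(100.0, 100.0, 100.0, 90.0, 90.0, 90.0, "P 1")


def random_rigid_transform(rng):
    """A uniformly random proper rotation + bounded translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-50.0, 50.0, 3)


def analyzed_crossover(built):
    """Run the detection pipeline on a built two-duplex assembly."""
    dups = find_duplexes(built.chains())
    xos = find_crossovers(dups, max_distance=30.0)
    assert len(xos) == 1
    return xos[0]


def crossover_from_atoms(atoms, max_distance=30.0):
    chains = {}
    for a in atoms:
        chains.setdefault(a.chain_id, []).append(a)
    dups = find_duplexes([(("x", c), ats) for c, ats in sorted(chains.items())])
    xos = find_crossovers(dups, max_distance=max_distance)
    assert len(xos) == 1
    return xos[0]
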