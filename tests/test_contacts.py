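"""Groove sectors, interaction-mode classification, anchors, cation bridges."""

import numpy as np
import pytest

from conftest import analyzed_crossover, crossover_from_atoms

from helixcross.contacts import (
    BRIDGE_CUTOFF,
    ContactMode,
    classify_mode,
    detect_anchor_contacts,
    detect_cation_bridges,
    groove_sector,
)
from helixcross.duplex import build_duplex, fit_linear_axis
from helixcross.model import AtomRecord
from helixcross.synthetic import (
    BuildParams,
    CrossoverSpec,
    add_ion,
    build_crossover,
    build_ideal_bdna,
    mirror_assembly,
)


def _duplex(built):
    ch = built.chains()
    a, b = built.chain_ids
    return build_duplex(ch[a], ch[b])


class TestGrooveSector:
    def test_point_on_plus_x_is_major(self, ideal_dodecamer):
        dup = _duplex(ideal_dodecamer)
        axis = fit_linear_axis(dup)
        mid = dup.pairs[6]
        pt = mid.origin + 8.0 * mid.x_axis
        sec = groove_sector(pt, dup, axis)
        assert sec.sector == "major"
        assert sec.radial_distance == pytest.approx(8.0, abs=0.05)

    def test_point_on_minus_x_is_minor(self, ideal_dodecamer):
        dup = _duplex(ideal_dodecamer)
        mid = dup.pairs[6]
        sec = groove_sector(mid.origin - 8.0 * mid.x_axis, dup)
        assert sec.sector == "minor"

    def test_sectors_partition_the_circle(self, ideal_dodecamer):
        dup = _duplex(ideal_dodecamer)
        axis = fit_linear_axis(dup)
        mid = dup.pairs[6]
        for theta in np.linspace(-179.5, 180.0, 144):
            v = np.cos(np.deg2rad(theta)) * mid.x_axis + np.sin(np.deg2rad(theta)) * mid.y_axis
            sec = groove_sector(mid.origin + 8.0 * v, dup, axis)
            assert sec.sector in ("major", "minor", "backbone_side")

    def test_own_cytosine_n4_sits_in_major_sector(self):
        """Chemical-geometry oracle: N4 is a major-groove edge atom, so the
        duplex's own cytosine N4 atoms must project into the major sector."""
        hits = total = 0
        for seq in ("ACCGGCGCCACA", "CCGCCGGCGG", "GCAAACGTTTGC"):
            dup = _duplex(build_ideal_bdna(BuildParams(seq)))
            axis = fit_linear_axis(dup)
            for res in dup.all_residues():
                if res.letter == "C" and "N4" in res.atoms:
                    total += 1
                    if groove_sector(res.atoms["N4"].position, dup, axis).sector == "major":
                        hits += 1
        assert hits / total >= 0.95

    def test_point_beyond_ends_flagged(self, ideal_dodecamer):
        dup = _duplex(ideal_dodecamer)
        axis = fit_linear_axis(dup)
        far = axis.at(axis.seg_max + 10.0) + 8.0 * dup.pairs[-1].x_axis
        assert groove_sector(far, dup, axis).out_of_range


class TestClassifyMode:
    def test_groove_backbone_fixture(self, gb_crossover):
        xo = analyzed_crossover(gb_crossover)
        report = classify_mode(xo)
        assert report.mode is ContactMode.MAJOR_GROOVE_BACKBONE
        assert len(report.penetrating_phosphates) >= 1
        assert all(p.groove == "major" for p in report.penetrating_phosphates)

    def test_major_major_fixture(self):
        xo = analyzed_crossover(
            build_crossover(CrossoverSpec(-60.0, 20.0, "groove_groove_major"))
        )
        report = classify_mode(xo)
        assert report.mode is ContactMode.MAJOR_MAJOR
        assert report.penetrating_phosphates == []

    def test_minor_minor_fixture(self):
        xo = analyzed_crossover(
            build_crossover(CrossoverSpec(-60.0, 20.0, "groove_groove_minor"))
        )
        assert classify_mode(xo).mode is ContactMode.MINOR_MINOR

    def test_mode_invariant_under_rotation_and_preserved_by_mirror(self, gb_crossover):
        rot = np.array([[0, -1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        moved = [a.moved(rot @ a.position + np.array([7.0, -3.0, 11.0]))
                 for a in gb_crossover.atoms()]
        assert classify_mode(crossover_from_atoms(moved)).mode is ContactMode.MAJOR_GROOVE_BACKBONE
        # mirroring flips handedness but grooves/backbone roles persist
        mirrored = crossover_from_atoms(mirror_assembly(gb_crossover.atoms()))
        assert mirrored.alpha_deg == pytest.approx(-60.0, abs=1e-9)
        assert classify_mode(mirrored).mode is ContactMode.MAJOR_GROOVE_BACKBONE


class TestAnchors:
    @pytest.mark.parametrize(
        "distance,expected_kinds",
        [(3.0, {"hbond_anchor"}), (4.0, {"proximal_anchor"}), (5.0, set())],
    )
    def test_n4_phosphate_distance_windows(self, gb_crossover, distance, expected_kinds):
        """The bold vs bold-italic distinction: N4 within 3.4 Å of a
        phosphate oxygen is a hydrogen-bond anchor, within [3.5, 4.5] Å a
        proximal anchor, beyond that nothing."""
        xo = analyzed_crossover(gb_crossover)
        report = classify_mode(xo)
        pen = report.penetrating_phosphates[0]
        host = xo.duplex_a if pen.host == "a" else xo.duplex_b
        # rebuild one cytosine N4 at the requested distance from OP1, placed
        # radially beyond OP1 so OP1 is provably the nearest phosphate oxygen
        op1 = pen.residue.atoms["OP1"].position
        p = pen.residue.atoms["P"].position
        u = (op1 - p) / np.linalg.norm(op1 - p)
        cyt = next(r for r in host.all_residues() if r.letter == "C" and "N4" in r.atoms)
        cyt.atoms["N4"].position = op1 + distance * u
        report = detect_anchor_contacts(report)
        kinds = {a.kind for a in report.anchors if a.base is cyt}
        assert kinds == expected_kinds
        for anchor in report.anchors:
            if anchor.base is cyt:
                assert anchor.distance == pytest.approx(distance, abs=1e-6)

    def test_hbond_and_proximal_sets_disjoint(self, gb_crossover):
        xo = analyzed_crossover(gb_crossover)
        report = detect_anchor_contacts(classify_mode(xo))
        ids_hb = {id(a.base) for a in report.anchors if a.kind == "hbond_anchor"}
        ids_px = {id(a.base) for a in report.anchors if a.kind == "proximal_anchor"}
        assert not (ids_hb & ids_px)

    def test_groove_groove_modes_have_no_anchors(self):
        xo = analyzed_crossover(
            build_crossover(CrossoverSpec(-60.0, 20.0, "groove_groove_major"))
        )
        report = detect_anchor_contacts(classify_mode(xo))
        assert report.anchors == []


class TestCationBridges:
    def _bridge_point(self, xo):
        return 0.5 * (xo.point_a + xo.point_b)

    def test_mg_contacting_both_duplexes_bridges(self, gb_crossover):
        xo = analyzed_crossover(gb_crossover)
        # place Mg midway between the closest atom pair across the interface
        da = np.array([a.position for a in xo.duplex_a.atoms()])
        db = np.array([a.position for a in xo.duplex_b.atoms()])
        d2 = ((da[:, None, :] - db[None, :, :]) ** 2).sum(-1)
        ia, ib = np.unravel_index(np.argmin(d2), d2.shape)
        mid = 0.5 * (da[ia] + db[ib])
        ion = AtomRecord(99999, "MG", "Mg", "MG", "Z", 1, mid, is_hetero=True)
        report = detect_cation_bridges(classify_mode(xo), [ion], cutoff=BRIDGE_CUTOFF)
        assert len(report.bridges) == 1
        assert report.bridges[0].charge_class == "divalent"

    def test_one_sided_mg_does_not_bridge(self, gb_crossover):
        xo = analyzed_crossover(gb_crossover)
        spot = xo.duplex_a.atoms()[0].position + np.array([0.0, 0.0, 2.1])
        ion = AtomRecord(99999, "MG", "Mg", "MG", "Z", 1, spot, is_hetero=True)
        report = detect_cation_bridges(classify_mode(xo), [ion])
        assert report.bridges == []

    def test_sodium_bridge_flagged_non_divalent(self, gb_crossover):
        xo = analyzed_crossover(gb_crossover)
        pa = xo.point_a + 0.5 * (xo.point_b - xo.point_a)
        # put Na at the closest-approach midpoint scaled to contact both
        da = np.array([a.position for a in xo.duplex_a.atoms()])
        db = np.array([a.position for a in xo.duplex_b.atoms()])
        ia = np.argmin(np.linalg.norm(da - pa, axis=1))
        ib = np.argmin(np.linalg.norm(db - pa, axis=1))
        mid = 0.5 * (da[ia] + db[ib])
        ion = AtomRecord(99999, "NA", "Na", "NA", "Z", 1, mid, is_hetero=True)
        report = detect_cation_bridges(classify_mode(xo), [ion])
        assert len(report.bridges) == 1
        assert report.bridges[0].charge_class == "monovalent"
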