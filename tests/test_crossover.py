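"""Closest approach and the signed (chiral) crossing angle."""

import numpy as np
import pytest

from conftest import analyzed_crossover, crossover_from_atoms, random_rigid_transform

from helixcross.duplex import HelicalAxisFit, find_duplexes
from helixcross.crossover import (
    DegenerateGeometryError,
    closest_approach,
    find_crossovers,
    signed_crossing_angle,
)
from helixcross.synthetic import (
    BuildParams,
    CrossoverSpec,
    build_crossover,
    build_ideal_bdna,
    mirror_assembly,
)


def _axis(point, direction, half_length=20.0):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return HelicalAxisFit(
        point=np.asarray(point, float), direction=d, rmsd=0.0,
        curvature_flag=False, seg_min=-half_length, seg_max=half_length,
    )


class TestClosestApproach:
    def test_perpendicular_offset_lines(self):
        a = _axis([0, 0, 0], [0, 0, 1])
        b = _axis([18, 0, 0], [0, 1, 0])
        pa, pb, dist, parallel = closest_approach(a, b)
        assert dist == pytest.approx(18.0, abs=1e-12)
        assert not parallel
        np.testing.assert_allclose(pa, [0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(pb, [18, 0, 0], atol=1e-9)

    def test_identical_lines_flagged_parallel(self):
        a = _axis([0, 0, 0], [0, 0, 1])
        b = _axis([0, 0, 5], [0, 0, 1])
        _, _, dist, parallel = closest_approach(a, b)
        assert parallel
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_sampling(self):
        """Random segment pairs vs a refined dense-sampling minimum."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = rng.uniform(-30, 30, (2, 3))
            u = rng.standard_normal((2, 3))
            axes = [_axis(p[k], u[k], half_length=rng.uniform(5, 25)) for k in range(2)]
            pa, pb, dist, _ = closest_approach(*axes)
            # two-stage brute force on the segment parameter grid
            t0 = np.linspace(0.0, 1.0, 101)
            lo = [0.0, 0.0]
            hi = [1.0, 1.0]
            for _stage in range(3):
                s = np.linspace(lo[0], hi[0], 101)
                t = np.linspace(lo[1], hi[1], 101)
                A = axes[0].at(axes[0].seg_min)[None, :] + s[:, None] * (
                    axes[0].direction * (axes[0].seg_max - axes[0].seg_min)
                )
                B = axes[1].at(axes[1].seg_min)[None, :] + t[:, None] * (
                    axes[1].direction * (axes[1].seg_max - axes[1].seg_min)
                )
                d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                step_s = (hi[0] - lo[0]) / 100
                step_t = (hi[1] - lo[1]) / 100
                lo = [max(0.0, s[i] - step_s), max(0.0, t[j] - step_t)]
                hi = [min(1.0, s[i] + step_s), min(1.0, t[j] + step_t)]
            brute = float(np.sqrt(d2[i, j]))
            assert dist == pytest.approx(brute, abs=1e-4)

    def test_zero_length_segment_raises(self):
        a = _axis([0, 0, 0], [0, 0, 1], half_length=0.0)
        b = _axis([5, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="zero-length"):
            closest_approach(a, b)


class TestSignedAngle:
    def test_constructed_fixture_returns_spec_angle(self):
        xo = analyzed_crossover(build_crossover(CrossoverSpec(60.0, 18.0, "none")))
        assert xo.alpha_deg == pytest.approx(60.0, abs=1e-6)
        assert xo.interaxial_distance == pytest.approx(18.0, abs=1e-6)
        assert xo.handedness == "right"

    def test_mirror_image_negates_angle(self):
        built = build_crossover(CrossoverSpec(60.0, 18.0, "none"))
        xo = crossover_from_atoms(mirror_assembly(built.atoms()))
        assert xo.alpha_deg == pytest.approx(-60.0, abs=1e-9)

    def test_exchange_symmetry(self):
        a = _axis([0, 0, 0], [0, 0, 1])
        b = _axis([15, 0, 0], [0, np.sin(1.0), np.cos(1.0)])
        pa, pb, _, _ = closest_approach(a, b)
        alpha_ab = signed_crossing_angle(a, b, (pa, pb))
        alpha_ba = signed_crossing_angle(b, a, (pb, pa))
        assert alpha_ab == pytest.approx(alpha_ba, abs=1e-9)

    def test_plus_90_boundary_convention(self):
        xo = analyzed_crossover(build_crossover(CrossoverSpec(90.0, 18.0, "none")))
        assert xo.alpha_deg == pytest.approx(90.0, abs=1e-6)
        mirrored = crossover_from_atoms(
            mirror_assembly(build_crossover(CrossoverSpec(90.0, 18.0, "none")).atoms())
        )
        assert mirrored.alpha_deg == pytest.approx(90.0, abs=1e-6)  # tie folds to +90

    def test_magnitude_bounded_by_90(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = _axis(rng.uniform(-20, 20, 3), rng.standard_normal(3))
            b = _axis(rng.uniform(-20, 20, 3), rng.standard_normal(3))
            pa, pb, dist, parallel = closest_approach(a, b)
            if parallel or dist < 1e-6:
                continue
            assert abs(signed_crossing_angle(a, b, (pa, pb))) <= 90.0

    def test_invariant_under_proper_rigid_motion(self):
        built = build_crossover(CrossoverSpec(-47.0, 19.0, "none"))
        ref = analyzed_crossover(built).alpha_deg
        rng = np.random.default_rng(8)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = [a.moved(rot @ a.position + trans) for a in built.atoms()]
            xo = crossover_from_atoms(moved)
            assert xo.alpha_deg == pytest.approx(ref, abs=1e-9)

    def test_coincident_axes_raise(self):
        a = _axis([0, 0, 0], [0, 0, 1])
        with pytest.raises(DegenerateGeometryError):
            signed_crossing_angle(a, a, (a.point, a.point))

    def test_gauss_linking_plectoneme_calibration(self):
        """An explicit right-handed interwound superhelix — the geometry of
        underwound, negatively supercoiled DNA — must give a negative
        (left-handed) crossing angle; its mirror a positive one.

        This pins the sign convention independently of the builder: the two
        strands of the plectoneme run antiparallel, t1=(0,R,k), t2=(0,R,-k)
        at closest approach (+-R, 0, 0), and the folded triple product gives
        sign -1 for k > 0."""
        R, k = 2.0, 12.0
        a = _axis([R, 0, 0], [0, R, k])
        b = _axis([-R, 0, 0], [0, R, -k])
        pa, pb, _, _ = closest_approach(a, b)
        assert signed_crossing_angle(a, b, (pa, pb)) < 0
        # mirror: left-handed superhelix ((+)sc geometry) -> positive
        am = _axis([-R, 0, 0], [0, R, k])
        bm = _axis([R, 0, 0], [0, R, -k])
        pam, pbm, _, _ = closest_approach(am, bm)
        assert signed_crossing_angle(am, bm, (pam, pbm)) > 0


class TestFindCrossovers:
    def test_beyond_cutoff_yields_nothing(self):
        d1 = build_ideal_bdna(BuildParams("ACCGGCGCCACA"), chain_ids=("A", "B"))
        d2 = build_ideal_bdna(BuildParams("ACCGGCGCCACA"), chain_ids=("C", "D"))
        rot = np.array([[1, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        d2.transform(rot, np.array([40.0, 0.0, 0.0]))
        chains = [(("x", c), ats) for b in (d1, d2) for c, ats in b.chains().items()]
        xos = find_crossovers(find_duplexes(chains))
        assert xos == []

    def test_fixture_pair_detected_once(self, gb_crossover):
        xos = find_crossovers(find_duplexes(gb_crossover.chains()))
        assert len(xos) == 1
        assert xos[0].alpha_deg == pytest.approx(60.0, abs=1e-6)

    def test_min_overlap_excludes_end_on_contacts(self):
        d1 = build_ideal_bdna(BuildParams("ACCGGCGCCACA"), chain_ids=("A", "B"))
        d2 = build_ideal_bdna(BuildParams("ACCGGCGCCACA"), chain_ids=("C", "D"))
        rot = np.array([[1, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        # closest approach at the very end of duplex 1's segment
        d2.transform(rot, np.array([15.0, 0.0, 25.0]))
        chains = [(("x", c), ats) for b in (d1, d2) for c, ats in b.chains().items()]
        assert find_crossovers(find_duplexes(chains)) == []
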