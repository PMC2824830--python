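"""Base-pair detection, reference frames, and helical axis fitting."""

import numpy as np
import pytest

from conftest import random_rigid_transform

from helixcross.duplex import (
    build_duplex,
    detect_base_pairs,
    fit_linear_axis,
    find_duplexes,
    group_nucleotides,
)
from helixcross.synthetic import BuildParams, build_ideal_bdna


def _chains(built):
    ch = built.chains()
    a, b = built.chain_ids
    return ch[a], ch[b]


class TestBasePairDetection:
    def test_ideal_dodecamer_gives_12_ordered_wc_pairs(self, ideal_dodecamer):
        pairs = detect_base_pairs(*_chains(ideal_dodecamer))
        assert len(pairs) == 12
        assert all(p.pair_type == "WC" for p in pairs)
        numbers = [p.residue_i.number for p in pairs]
        assert numbers == sorted(numbers)
        assert "".join(p.residue_i.letter for p in pairs) == "ACCGGCGCCACA"

    def test_displaced_strands_give_no_pairs(self, ideal_dodecamer):
        ca, cb = _chains(ideal_dodecamer)
        cb = [a.moved(a.position + np.array([30.0, 0.0, 0.0])) for a in cb]
        assert detect_base_pairs(ca, cb) == []

    def test_complementary_sequences(self, ideal_dodecamer):
        dup = build_duplex(*_chains(ideal_dodecamer))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        assert dup.sequence_ii == "".join(comp[c] for c in dup.sequence_i)[::-1]

    def test_modified_bases_pair_via_parents(self):
        built = build_ideal_bdna(BuildParams("AMICGT"))  # 5mC and inosine
        pairs = detect_base_pairs(*_chains(built))
        assert len(pairs) == 6
        letters = [p.residue_i.letter for p in pairs]
        assert letters == list("ACICGT")  # 5CM maps to C


class TestFrames:
    def test_gc_frame_points_into_major_groove(self):
        built = build_ideal_bdna(BuildParams("GGGG"))
        dup = build_duplex(*_chains(built))
        for pair in dup.pairs:
            cyt = pair.residue_j  # strand II cytosines
            assert cyt.letter == "C"
            x, o = pair.x_axis, pair.origin
            assert x @ (cyt.atoms["N4"].position - o) > 0
            assert x @ (cyt.atoms["O2"].position - o) < 0

    @pytest.mark.parametrize("seq", ["ACCGGCGCCACA", "CTCTCGAGAG", "GCAAACGTTTGC"])
    def test_frames_orthonormal(self, seq):
        built = build_ideal_bdna(BuildParams(seq, noise_sigma=0.05, seed=3))
        dup = build_duplex(*_chains(built))
        for pair in dup.pairs:
            M = np.stack([pair.x_axis, pair.y_axis, pair.z_axis])
            np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)

    def test_successive_frames_rotate_by_build_twist(self, ideal_dodecamer):
        dup = build_duplex(*_chains(ideal_dodecamer))
        twists = []
        for p0, p1 in zip(dup.pairs, dup.pairs[1:]):
            assert p0.z_axis @ p1.z_axis > np.cos(np.deg2rad(2.0))
            tw = np.degrees(np.arctan2(
                np.cross(p0.x_axis, p1.x_axis) @ p0.z_axis, p0.x_axis @ p1.x_axis
            ))
            twists.append(tw)
        assert np.mean(twists) == pytest.approx(36.0, abs=1.0)


class TestAxisFit:
    def test_collinear_origins_exact(self):
        origins = np.array([[0.0, 0.0, 3.38 * i] for i in range(10)])
        fit = fit_linear_axis(origins)
        np.testing.assert_array_equal(fit.direction, [0.0, 0.0, 1.0])
        assert fit.rmsd == 0.0
        assert not fit.curvature_flag

    def test_ideal_duplex_matches_builder_axis(self, ideal_dodecamer):
        dup = build_duplex(*_chains(ideal_dodecamer))
        fit = fit_linear_axis(dup)
        assert abs(fit.direction @ ideal_dodecamer.axis_direction) >= 0.9999
        assert fit.rmsd < 0.5

    def test_direction_signed_along_strand_i(self, ideal_dodecamer):
        dup = build_duplex(*_chains(ideal_dodecamer))
        fit = fit_linear_axis(dup)
        assert fit.direction @ (dup.pairs[-1].origin - dup.pairs[0].origin) > 0

    def test_circular_arc_trips_curvature_flag(self):
        """Arc radius 50 Å spanning 90°: rms to the best line has the
        analytic chord-sagitta value R*sqrt(1/2 + sin(2t)/(4t) - (sin t/t)^2)."""
        R, t0 = 50.0, np.pi / 4
        phi = np.linspace(-t0, t0, 721)
        pts = np.stack([R * np.cos(phi), R * np.sin(phi), np.zeros_like(phi)], axis=1)
        fit = fit_linear_axis(pts)
        analytic = R * np.sqrt(
            0.5 + np.sin(2 * t0) / (4 * t0) - (np.sin(t0) / t0) ** 2
        )
        assert fit.rmsd == pytest.approx(analytic, rel=0.01)
        assert fit.curvature_flag

    def test_equivariance_under_rigid_motion(self, ideal_dodecamer):
        dup = build_duplex(*_chains(ideal_dodecamer))
        fit0 = fit_linear_axis(dup)
        rng = np.random.default_rng(5)
        for _ in range(10):
            rot, trans = random_rigid_transform(rng)
            moved = dup.origins() @ rot.T + trans
            fit1 = fit_linear_axis(moved)
            np.testing.assert_allclose(fit1.point, rot @ fit0.point + trans, atol=1e-9)
            assert abs(fit1.direction @ (rot @ fit0.direction)) == pytest.approx(1.0, abs=1e-9)
            assert fit1.rmsd == pytest.approx(fit0.rmsd, abs=1e-9)

    def test_strand_swap_flips_axis_sign_only(self, ideal_dodecamer):
        ca, cb = _chains(ideal_dodecamer)
        fwd = fit_linear_axis(build_duplex(ca, cb))
        rev = fit_linear_axis(build_duplex(cb, ca))
        assert fwd.direction @ rev.direction == pytest.approx(-1.0, abs=1e-9)
        # the unsigned axis line is unchanged
        delta = rev.point - fwd.point
        assert np.linalg.norm(np.cross(delta, fwd.direction)) < 1e-6

    def test_degenerate_cloud_raises(self):
        with pytest.raises(ValueError, match="degenerate|coincide"):
            fit_linear_axis(np.zeros((5, 3)))

    def test_rmsd_monotone_in_noise(self):
        rmsds = []
        for sigma in (0.0, 0.1, 0.3):
            vals = []
            for seed in range(10):
                built = build_ideal_bdna(
                    BuildParams("ACCGGCGCCACA", noise_sigma=sigma, seed=seed)
                )
                dup = build_duplex(*_chains(built))
                vals.append(fit_linear_axis(dup).rmsd)
            rmsds.append(np.mean(vals))
        assert rmsds[0] < rmsds[1] < rmsds[2]


def test_find_duplexes_pools_chains(gb_crossover):
    dups = find_duplexes(gb_crossover.chains())
    assert len(dups) == 2
    sources = {tuple(k[1] for k in d.source) for d in dups}
    assert sources == {("A", "B"), ("C", "D")}
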