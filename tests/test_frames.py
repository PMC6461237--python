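"""Frenet/CαO frame construction, backbone angles, spherical coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbrecon import (SphericalDirection, backbone_angles, cao_frames,
                     frame_coordinates, frenet_frames, place_point,
                     stereographic_project, stereographic_unproject)
from cbrecon.frames import Frame

from conftest import apply_motion, manual_trace, random_rigid_motion


def ideal_helix_trace(n=20, radius=2.27, rise=1.51, per_turn=3.6):
    """Parametric alpha-helix Cα trace."""
    i = np.arange(n)
    ang = 2 * np.pi * i / per_turn
    return manual_trace(np.column_stack([radius * np.cos(ang),
                                         radius * np.sin(ang), rise * i]))


class TestFrenetFrames:
    def test_right_angle_chain_hand_case(self):
        tr = manual_trace([(0, 0, 0), (0, 0, 1), (1, 0, 1)])
        fr = frenet_frames(tr)
        assert list(fr.valid) == [False, True, False]
        n, b, t = fr.axes[1]
        np.testing.assert_allclose(b, [0, 1, 0], atol=1e-14)
        np.testing.assert_allclose(t, [1, 0, 0], atol=1e-14)
        np.testing.assert_allclose(n, [0, 0, -1], atol=1e-14)
        ang = backbone_angles(fr)
        assert ang.kappa[0] == pytest.approx(np.pi / 2, abs=1e-14)

    def test_collinear_points_invalidate_the_frame(self):
        tr = manual_trace([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        fr = frenet_frames(tr)
        assert not fr.valid[1]

    def test_ideal_helix_frames_are_orthonormal(self):
        fr = frenet_frames(ideal_helix_trace())
        assert fr.valid[1:-1].all()
        for i in np.nonzero(fr.valid)[0]:
            a = fr.axes[i]
            np.testing.assert_allclose(a @ a.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(a) == pytest.approx(1.0, abs=1e-10)

    def test_break_interrupts_frames(self):
        tr = manual_trace([(0, 0, 0), (0, 0, 3.8), (3.8, 0, 3.8),
                           (30, 0, 0), (30, 0, 3.8), (33.8, 0, 3.8)])
        from cbrecon import detect_breaks
        detect_breaks(tr)
        assert tr.break_after == {2}
        fr = frenet_frames(tr)
        assert list(fr.valid) == [False, True, False, False, True, False]


class TestBackboneAngles:
    def test_planar_chain_has_zero_torsion(self):
        rng = np.random.default_rng(0)
        # random in-plane turns, never collinear
        ang = np.cumsum(rng.uniform(0.3, 1.2, 10))
        ca = np.cumsum(3.8 * np.column_stack([np.cos(ang), np.sin(ang),
                                              np.zeros(10)]), axis=0)
        a = backbone_angles(frenet_frames(manual_trace(ca)))
        np.testing.assert_allclose(a.tau[a.tau_valid], 0.0, atol=1e-10)

    def test_mirror_reflection_preserves_kappa_negates_tau(self):
        tr = ideal_helix_trace()
        a = backbone_angles(frenet_frames(tr))
        mirrored = manual_trace(tr.ca_array() * np.array([1, 1, -1]))
        am = backbone_angles(frenet_frames(mirrored))
        np.testing.assert_allclose(am.kappa[a.kappa_valid],
                                   a.kappa[a.kappa_valid], atol=1e-10)
        dtau = np.mod(am.tau[a.tau_valid] + a.tau[a.tau_valid] + np.pi,
                      2 * np.pi) - np.pi
        np.testing.assert_allclose(dtau, 0.0, atol=1e-10)

    def test_rigid_motion_equivariance(self):
        tr = ideal_helix_trace()
        a = backbone_angles(frenet_frames(tr))
        rot, shift = random_rigid_motion(np.random.default_rng(1))
        moved = manual_trace(tr.ca_array() @ rot.T + shift)
        am = backbone_angles(frenet_frames(moved))
        np.testing.assert_allclose(am.kappa[a.kappa_valid],
                                   a.kappa[a.kappa_valid], atol=1e-10)
        np.testing.assert_allclose(am.tau[a.tau_valid],
                                   a.tau[a.tau_valid], atol=1e-10)


class TestCaoFrames:
    def test_in_plane_oxygen_hand_case(self):
        tr = manual_trace([(0, 0, 0), (3.8, 0, 0)],
                          o=[(1.2, 2.0, 0.0), None])
        fr = cao_frames(tr)
        assert fr.valid[0]
        u, v, w = fr.axes[0]
        np.testing.assert_allclose(u, [1, 0, 0], atol=1e-14)
        np.testing.assert_allclose(w, [0, 0, 1], atol=1e-14)
        np.testing.assert_allclose(v, [0, 1, 0], atol=1e-14)
        np.testing.assert_allclose(fr.origin[0], [1.2, 2.0, 0.0])

    def test_oxygen_on_axis_is_degenerate(self):
        tr = manual_trace([(0, 0, 0), (3.8, 0, 0)], o=[(1.9, 0, 0), None])
        assert not cao_frames(tr).valid[0]

    def test_random_inputs_give_right_handed_orthonormal_frames(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ca0 = rng.uniform(-10, 10, 3)
            d = rng.normal(size=3)
            d *= 3.8 / np.linalg.norm(d)
            o = ca0 + rng.uniform(1.5, 3.0) * rng.normal(size=3) / 3
            tr = manual_trace([ca0, ca0 + d], o=[o, None])
            fr = cao_frames(tr)
            if not fr.valid[0]:
                continue
            a = fr.axes[0]
            np.testing.assert_allclose(a @ a.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(a) == pytest.approx(1.0, abs=1e-10)


class TestFrameCoordinates:
    def _frame(self):
        tr = manual_trace([(0, 0, 0), (0, 0, 3.8), (3.8, 0, 3.8)])
        return frenet_frames(tr).frame(1)

    def test_axis_directions(self):
        fr = self._frame()
        n, b, t = fr.axes
        d = frame_coordinates(fr, fr.origin + 1.55 * t)
        assert (d.latitude, d.longitude) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert d.radius == pytest.approx(1.55, abs=1e-12)
        d = frame_coordinates(fr, fr.origin + n)
        assert (d.latitude, d.longitude) == pytest.approx((np.pi / 2, 0.0), abs=1e-12)
        d = frame_coordinates(fr, fr.origin + b)
        assert (d.latitude, d.longitude) == pytest.approx((np.pi / 2, np.pi / 2),
                                                          abs=1e-12)

    def test_zero_radius_is_an_error(self):
        fr = self._frame()
        with pytest.raises(ValueError, match="origin"):
            frame_coordinates(fr, fr.origin)

    def test_place_measure_round_trip(self):
        fr = self._frame()
        rng = np.random.default_rng(3)
        for _ in range(200):
            d = SphericalDirection(latitude=rng.uniform(0.01, np.pi - 0.01),
                                   longitude=rng.uniform(-np.pi, np.pi),
                                   radius=rng.uniform(0.5, 5.0))
            back = frame_coordinates(fr, place_point(fr, d))
            assert back.latitude == pytest.approx(d.latitude, abs=1e-12)
            assert back.longitude == pytest.approx(d.longitude, abs=1e-12)
            assert back.radius == pytest.approx(d.radius, abs=1e-12)

    def test_spherical_outputs_invariant_under_rigid_motion(self):
        spec_tr = ideal_helix_trace(12)
        o = [tuple(np.asarray(r.ca) + (1.0, 1.5, 0.5)) for r in spec_tr.residues]
        tr = manual_trace(spec_tr.ca_array(), o=o)
        fr = frenet_frames(tr)
        rng = np.random.default_rng(9)
        rot, shift = random_rigid_motion(rng)
        moved = apply_motion(tr, rot, shift)
        frm = frenet_frames(moved)
        for i in np.nonzero(fr.valid)[0]:
            d0 = frame_coordinates(fr.frame(i), tr.residues[i].o)
            d1 = frame_coordinates(frm.frame(i), moved.residues[i].o)
            assert d1.latitude == pytest.approx(d0.latitude, abs=1e-10)
            assert d1.longitude == pytest.approx(d0.longitude, abs=1e-10)


def test_export_angles_tsv(tmp_path):
    a = backbone_angles(frenet_frames(ideal_helix_trace(8)))
    path = tmp_path / "angles.tsv"
    from cbrecon import export_angles
    export_angles(a, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["residue_index", "kappa", "tau",
                                    "kappa_valid", "tau_valid"]
    assert len(lines) == 9
    row = lines[3].split("\t")  # an interior residue: both angles valid
    assert float(row[1]) == pytest.approx(a.kappa[2])
    assert float(row[2]) == pytest.approx(a.tau[2])


class TestStereographic:
    def test_hand_values(self):
        np.testing.assert_allclose(stereographic_project([0.0], [1.3]),
                                   [[0.0, 0.0]], atol=1e-15)
        np.testing.assert_allclose(stereographic_project([np.pi / 2], [np.pi / 2]),
                                   [[0.0, 1.0]], atol=1e-15)

    def test_south_pole_is_an_error(self):
        with pytest.raises(ValueError, match="south pole"):
            stereographic_project([np.pi], [0.0])

    @settings(derandomize=True, max_examples=200)
    @given(kappa=st.floats(0.0, np.pi - 1e-6),
           tau=st.floats(-np.pi, np.pi - 1e-9))
    def test_round_trip_identity(self, kappa, tau):
        xy = stereographic_project([kappa], [tau])
        k, t = stereographic_unproject(xy)
        assert k[0] == pytest.approx(kappa, abs=1e-12)
        if kappa > 1e-9:  # longitude undefined at the pole
            d = np.mod(t[0] - tau + np.pi, 2 * np.pi) - np.pi
            assert abs(d) < 1e-12
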