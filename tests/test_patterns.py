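"""Pattern detection: order parameter, critical points, index, tracking."""

import numpy as np
import pandas as pd
import pytest

import cortexwave as cw
from cortexwave import patterns as P
from cortexwave.datatypes import CriticalPoint, PatternTrack, PhaseVelocityField


def _field(v, t=0):
    return PhaseVelocityField(v=np.asarray(v, dtype=complex), t=t)


def _field_from_fn(fn, shape=(24, 24), t=0):
    """Field with v = fn(z) where z = col + i*row (complex position)."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return _field(fn(cols + 1j * rows), t=t)


def _point(t, loc, ptype, index, radius=1):
    J = np.diag([1.0, -1.0]) if ptype == "saddle" else np.eye(2)
    return CriticalPoint(t=t, location=loc, jacobian=J, trace=float(np.trace(J)),
                         determinant=float(np.linalg.det(J)),
                         eigenvalues=(1.0, -1.0), type=ptype, subtype="none",
                         poincare_index=index, radius=radius)


class TestOrderParameter:
    def test_uniform_field_is_one(self):
        assert P.order_parameter(_field(np.full((10, 12), 2.0 - 1.0j))) == \
            pytest.approx(1.0)

    def test_antiparallel_halves_cancel(self):
        v = np.ones((10, 12), dtype=complex)
        v[5:] = -1.0
        assert P.order_parameter(_field(v)) == pytest.approx(0.0, abs=1e-12)

    def test_random_directions_match_rayleigh_mean(self):
        """For N unit vectors with iid uniform angles the expected order
        parameter is sqrt(pi) / (2 * sqrt(N))."""
        N = 44 * 52
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi, size=N)
            vals.append(P.order_parameter(_field(np.exp(1j * theta).reshape(44, 52))))
        expected = np.sqrt(np.pi) / (2.0 * np.sqrt(N))
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)

    def test_zero_field_raises(self):
        with pytest.raises(ValueError, match="zero mean speed"):
            P.order_parameter(_field(np.zeros((8, 8))))

    def test_respects_reliability_mask(self):
        v = np.ones((10, 10), dtype=complex)
        v[0, 0] = -50.0  # junk pixel, masked out
        rel = np.ones((10, 10), dtype=bool)
        rel[0, 0] = False
        f = PhaseVelocityField(v=v, reliability=rel)
        assert P.order_parameter(f) == pytest.approx(1.0)


class TestFrameClassification:
    def test_plane_label_for_parallel_flow(self):
        fields = [_field(np.full((10, 10), 1.0 + 0.2j), t=t) for t in range(6)]
        out = P.summarize_frames(fields)
        assert all(s.label == "plane" for s in out)
        assert all(s.order_parameter == pytest.approx(1.0) for s in out)

    def test_speed_collapse_labelled_standing(self):
        rng = np.random.default_rng(1)
        fields = []
        for t in range(20):
            speed = 0.01 if t == 10 else 1.0 + 0.02 * rng.normal()
            fields.append(_field(np.full((10, 10), speed + 0j), t=t))
        out = P.summarize_frames(fields)
        assert out[10].label == "standing"
        assert sum(s.label == "standing" for s in out) == 1

    def test_disordered_directions_labelled_other(self):
        rng = np.random.default_rng(2)
        noise = _field(np.exp(1j * rng.uniform(0, 2 * np.pi, (20, 20))), t=0)
        summary = P.classify_frame(noise, speed_history=[1.0] * 10)
        assert summary.label == "other"

    def test_history_is_required(self):
        with pytest.raises(ValueError, match="speed_history"):
            P.classify_frame(_field(np.ones((8, 8))))

    def test_mean_direction_convention(self):
        # pure +u flow propagates laterally: angle 0
        assert P.mean_direction(_field(np.ones((8, 8)))) == pytest.approx(0.0)
        # pure -w flow (towards row 0 = anterior): angle pi/2
        assert P.mean_direction(_field(np.full((8, 8), -1.0j))) == \
            pytest.approx(np.pi / 2)


class TestCriticalPoints:
    def test_uniform_field_has_no_critical_points(self):
        assert P.find_critical_points(_field(np.ones((12, 12)))) == []

    @pytest.mark.parametrize("center", [(7.0, 9.0), (7.25, 9.75), (3.5, 14.5)])
    def test_linear_zero_located_subpixel(self, center):
        f = cw.generate_linear_field(np.array([[1.0, 0.3], [-0.2, 1.0]]),
                                     center, (18, 22))
        pts = P.find_critical_points(f)
        assert len(pts) == 1
        assert pts[0][0] == pytest.approx(center[0], abs=1e-9)
        assert pts[0][1] == pytest.approx(center[1], abs=1e-9)

    def test_two_zeros_of_quadratic_field_found(self):
        z1, z2 = 6 + 7j, 16 + 13j
        f = _field_from_fn(lambda z: 0.05 * (z - z1) * (z - z2))
        pts = P.find_critical_points(f)
        assert len(pts) == 2
        found = sorted((round(r, 6), round(c, 6)) for r, c in pts)
        assert found == [(7.0, 6.0), (13.0, 16.0)]

    def test_jacobian_sign_chart_on_random_matrices(self):
        """10^4 random Jacobians: type from (tau, Delta) signs, subtype from
        the discriminant, index from sign(Delta)."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            J = rng.normal(size=(2, 2))
            res = P.classify_jacobian(J)
            assert res is not None
            ptype, subtype, index, tau, delta, eig = res
            assert tau == pytest.approx(np.trace(J))
            assert delta == pytest.approx(np.linalg.det(J))
            if delta < 0:
                assert ptype == "saddle" and index == -1 and subtype == "none"
                assert np.isreal(eig[0]) and eig[0].real * eig[1].real < 0
            else:
                assert ptype == ("source" if tau > 0 else "sink")
                assert index == 1
                expected_sub = "focus" if tau * tau - 4 * delta < 0 else "node"
                assert subtype == expected_sub
                if subtype == "focus":
                    assert abs(eig[0].imag) > 0

    def test_degenerate_jacobian_returns_none(self):
        assert P.classify_jacobian(np.zeros((2, 2)), eps=1e-12) is None
        # centre: rotation matrix generator, tau = 0, delta > 0
        assert P.classify_jacobian(np.array([[0.0, -1.0], [1.0, 0.0]])) is None

    def test_classify_critical_point_recovers_planted_jacobian(self):
        A = np.array([[0.7, -0.4], [0.9, 0.2]])
        f = cw.generate_linear_field(A, (8.25, 10.5), (20, 24))
        cp = P.classify_critical_point(f, P.find_critical_points(f)[0])
        assert np.allclose(cp.jacobian, A, atol=1e-9)


class TestPoincareIndex:
    def test_source_loop_is_plus_one(self):
        f = cw.generate_linear_field(np.eye(2), (10.0, 10.0), (21, 21))
        assert P.poincare_index(f, P.square_loop((10, 10), 4)) == 1

    def test_saddle_loop_is_minus_one(self):
        f = cw.generate_linear_field(np.diag([1.0, -1.0]), (10.0, 10.0), (21, 21))
        assert P.poincare_index(f, P.square_loop((10, 10), 4)) == -1

    def test_empty_loop_is_zero(self):
        f = cw.generate_linear_field(np.eye(2), (4.0, 4.0), (24, 24))
        assert P.poincare_index(f, P.square_loop((16, 16), 4)) == 0

    def test_index_is_additive_over_enclosed_points(self):
        z1, z2 = 8 + 9j, 14 + 12j
        both = _field_from_fn(lambda z: 0.05 * (z - z1) * (z - z2))
        assert P.poincare_index(both, P.square_loop((11, 11), 9)) == 2
        mixed = _field_from_fn(
            lambda z: 0.05 * (z - z1) * np.conj(z - z2))
        assert P.poincare_index(mixed, P.square_loop((11, 11), 9)) == 0
        assert P.poincare_index(mixed, P.square_loop((9, 8), 2)) == 1
        assert P.poincare_index(mixed, P.square_loop((12, 14), 2)) == -1

    def test_loop_through_zero_rejected(self):
        f = cw.generate_linear_field(np.eye(2), (10.0, 14.0), (21, 21))
        with pytest.raises(ValueError, match="winding undefined"):
            P.poincare_index(f, P.square_loop((10, 10), 4))

    def test_square_loop_geometry(self):
        loop = P.square_loop((5.0, 7.0), 3)
        assert loop.shape == (24, 2)  # 8 * half_width points
        assert np.abs(loop - [5.0, 7.0]).max() == 3.0


class TestPatternRadius:
    def test_source_radius_limited_by_field_edge(self):
        f = cw.generate_linear_field(np.eye(2), (10.0, 10.0), (21, 21))
        [cp] = P.analyze_frame(f)
        assert cp.type == "source"
        assert cp.radius == 10

    def test_radius_stops_where_flow_reverses(self):
        rows, cols = np.mgrid[0:25, 0:25].astype(float)
        dx, dy = cols - 12.0, rows - 12.0
        dist = np.hypot(dx, dy)
        sign = np.where(dist <= 5.0, 1.0, -1.0)  # outward inside, inward beyond
        f = _field(sign * (dx + 1j * dy))
        cp = P.classify_critical_point(f, (12.0, 12.0))
        assert cp.type == "source"
        r = P.pattern_radius(f, cp)
        assert 4 <= r <= 5

    def test_saddle_signature_radius(self):
        f = cw.generate_linear_field(np.diag([1.0, -1.0]), (10.0, 10.0), (21, 21))
        [cp] = P.analyze_frame(f)
        assert cp.type == "saddle"
        assert cp.radius == 10


class TestTracking:
    def test_stationary_point_forms_single_track(self):
        frames = [[_point(t, (5.0, 5.0 + 0.1 * t), "source", 1)] for t in range(5)]
        tracks = P.track_patterns(frames)
        assert len(tracks) == 1
        assert tracks[0].duration == 5
        assert tracks[0].frames == [0, 1, 2, 3, 4]

    def test_jump_beyond_tolerance_starts_new_track(self):
        frames = [[_point(0, (5.0, 5.0), "source", 1)],
                  [_point(1, (5.0, 9.0), "source", 1)]]
        tracks = P.track_patterns(frames, link_tol=2.0)
        assert len(tracks) == 2

    def test_type_mismatch_not_linked(self):
        frames = [[_point(0, (5.0, 5.0), "source", 1)],
                  [_point(1, (5.0, 5.0), "sink", 1)]]
        assert len(P.track_patterns(frames)) == 2

    def test_greedy_matching_prefers_nearest(self):
        frames = [[_point(0, (5.0, 5.0), "source", 1),
                   _point(0, (5.0, 8.0), "source", 1)],
                  [_point(1, (5.0, 5.5), "source", 1),
                   _point(1, (5.0, 7.5), "source", 1)]]
        tracks = P.track_patterns(frames, link_tol=3.0)
        assert len(tracks) == 2
        assert all(t.duration == 2 for t in tracks)
        cols = sorted(t.points[1].location[1] for t in tracks)
        assert cols == [5.5, 7.5]

    def test_filter_tracks_thresholds(self):
        long_big = PatternTrack(points=[_point(t, (5, 5), "source", 1, radius=3)
                                        for t in range(6)])
        short = PatternTrack(points=[_point(0, (8, 8), "sink", 1, radius=5)])
        long_small = PatternTrack(points=[_point(t, (2, 2), "saddle", -1, radius=1)
                                          for t in range(6)])
        tracks = [long_big, short, long_small]
        assert P.filter_tracks(tracks, d=5, r=3) == [long_big]
        assert P.filter_tracks(tracks, d=1, r=1) == tracks

    def test_detection_surface_monotone_and_normalised(self):
        rng = np.random.default_rng(3)
        tracks = []
        for _ in range(60):
            dur = int(rng.integers(1, 12))
            rad = int(rng.integers(1, 8))
            tracks.append(PatternTrack(points=[
                _point(t, (5, 5), "source", 1, radius=rad) for t in range(dur)]))
        d_range, r_range = range(1, 10), range(1, 7)
        s = P.detection_probability_surface(tracks, d_range, r_range)
        assert s[0, 0] == 1.0
        assert np.all(np.diff(s, axis=0) <= 0)
        assert np.all(np.diff(s, axis=1) <= 0)

    def test_detection_surface_empty_rejected(self):
        with pytest.raises(ValueError, match="no tracks"):
            P.detection_probability_surface([], [1], [1])


class TestWindowSweep:
    def test_plane_wave_is_plane_at_every_partition(self):
        fields = [_field(np.full((16, 16), 1.0 + 0.0j), t=t) for t in range(6)]
        df = P.window_sweep(fields)
        assert list(df["n_windows"]) == [1, 2, 4, 16]
        assert np.allclose(df["p_plane"], 1.0)
        assert np.allclose(df["p_standing"] + df["p_plane"] + df["p_other"], 1.0)

    def test_unsupported_partition_rejected(self):
        fields = [_field(np.ones((16, 16)))]
        with pytest.raises(ValueError, match="partition"):
            P.window_sweep(fields, partitions=(3,))


class TestCensusAndIndexSeries:
    def test_census_counts_combinations(self):
        tracks = [
            PatternTrack(points=[_point(0, (5, 5), "source", 1),
                                 _point(1, (5, 5), "source", 1)]),
            PatternTrack(points=[_point(1, (9, 9), "sink", 1)]),
            PatternTrack(points=[_point(2, (3, 3), "saddle", -1)]),
        ]
        hist, counts = P.coexistence_census(tracks, frames=range(4))
        assert hist["source"] == 1          # frame 0
        assert hist["source+sink"] == 1     # frame 1
        assert hist["saddle"] == 1          # frame 2
        assert hist.sum() == 3              # frame 3 has nothing
        assert counts == {0: 1, 1: 2, 2: 1, 3: 0}

    def test_pairwise_creation_conserves_total_index(self):
        """A sink-saddle pair appearing together changes the count by two
        but the total index by zero; a point leaving through the boundary
        changes the total by its own index."""
        z1, z2, z3 = 6 + 6j, 16 + 8j, 10 + 16j
        fns = [
            lambda z: 0.05 * (z - z1),                                  # +1
            lambda z: 0.002 * (z - z1) * (z - z2) * np.conj(z - z3),    # +1
            lambda z: 0.05 * (z - z2) * np.conj(z - z3) / 10.0,         # 0
        ]
        pts_by_frame = [P.analyze_frame(_field_from_fn(fn, (23, 23), t=t))
                        for t, fn in enumerate(fns)]
        totals = [sum(p.poincare_index for p in pts) for pts in pts_by_frame]
        assert totals == [1, 1, 0]
        assert [len(p) for p in pts_by_frame] == [1, 3, 2]
        deltas, dist = P.index_change_series(pts_by_frame)
        assert list(deltas) == [0, -1]
        assert dist[0] == pytest.approx(0.5)
        assert dist[-1] == pytest.approx(0.5)

    def test_empty_series(self):
        deltas, dist = P.index_change_series([[]])
        assert deltas.size == 0 and dist.empty
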