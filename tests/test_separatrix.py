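"""Separatrix objects: QIF point, 2D line, 3D plane, traced manifolds."""

import numpy as np
import pytest

from sepx import (
    bisect_boundary,
    classify_states,
    find_equilibria,
    get_model,
    integrate,
    pwl2d_separatrix,
    pwl3d_separatrix,
    qif_rheobase,
    qif_threshold,
    separatrix_for,
    trace_manifold,
)
from sepx.exceptions import BracketError, NoThresholdError, SepxError
from sepx.separatrix import make_classifier

from conftest import FAST

# frozen oracle values for the 2D defaults (eigenvalues (0.3 +- sqrt(0.13))/2)
K_THETA = 0.35 + np.sqrt(0.13) / 2.0  # = k_m - lambda_stable
B_THETA = -1.5 * (0.45 - K_THETA) / (0.45 - 0.5)


class TestQIFPoint:
    def test_no_drive_returns_vt_vr(self, qif):
        tp = qif_threshold(qif, 0.0)
        assert tp.theta == pytest.approx(qif.v_t, abs=1e-12)
        assert tp.v_rest == pytest.approx(qif.v_r, abs=1e-12)

    def test_root_formula_at_ie_50(self, qif):
        tp = qif_threshold(qif, 50.0)
        assert tp.theta == pytest.approx((30 + np.sqrt(700)) / 2, rel=1e-12)
        assert tp.v_rest == pytest.approx((30 - np.sqrt(700)) / 2, rel=1e-12)

    def test_rheobase_value(self, qif):
        assert qif_rheobase(qif) == pytest.approx(225.0)
        assert qif_rheobase(get_model("qif", v_t=10.0, v_peak=20.0)) == pytest.approx(25.0)

    def test_threshold_and_rest_merge_at_rheobase(self, qif):
        tp = qif_threshold(qif, 0.999 * qif_rheobase(qif))
        assert tp.theta - tp.v_rest == pytest.approx(
            np.sqrt(4 * 225 * 0.001), rel=1e-9
        )
        with pytest.raises(NoThresholdError):
            qif_threshold(qif, qif_rheobase(qif))

    def test_monotone_in_drive(self, qif):
        ies = np.linspace(0.0, 0.95 * qif_rheobase(qif), 30)
        pts = [qif_threshold(qif, i) for i in ies]
        thetas = np.array([p.theta for p in pts])
        rests = np.array([p.v_rest for p in pts])
        assert np.all(np.diff(thetas) < 0)  # depolarization lowers threshold
        assert np.all(np.diff(rests) > 0)  # ... and raises the rest


class TestPWL2DLine:
    def test_slope_and_intercept_match_eigen_oracle(self, pwl2d):
        line = pwl2d_separatrix(pwl2d, 0.0)
        assert line.k_theta == pytest.approx(K_THETA, abs=1e-12)
        assert line.b_theta == pytest.approx(B_THETA, abs=1e-12)

    def test_slope_ordering(self, pwl2d):
        line = pwl2d_separatrix(pwl2d, 0.0)
        assert line.k_theta > pwl2d.f.k_m > pwl2d.k_w

    def test_line_passes_through_saddle(self, pwl2d):
        # saddle of the middle segment sits at (30, k_w * 30)
        line = pwl2d_separatrix(pwl2d, 0.0)
        assert line.w_of(30.0) == pytest.approx(13.5, abs=1e-10)

    def test_drive_shifts_intercept_linearly_slope_fixed(self, pwl2d):
        l0, l1, l2 = (pwl2d_separatrix(pwl2d, i) for i in (0.0, 1.0, 2.0))
        assert l0.k_theta == l1.k_theta == l2.k_theta
        assert (l1.b_theta - l0.b_theta) == pytest.approx(
            l2.b_theta - l1.b_theta, rel=1e-12
        )
        assert l1.b_theta > l0.b_theta  # depolarizing current raises the line

    def test_non_saddle_middle_segment_rejected(self):
        # slope of w-nullcline above the middle segment: no saddle, no line
        model = get_model("pwl2d", k_w=0.6)
        with pytest.raises(SepxError, match="saddle"):
            pwl2d_separatrix(model, 0.0)

    def test_classifier_agrees_with_firing_side(self, pwl2d):
        line = pwl2d_separatrix(pwl2d, 0.0)
        rng = np.random.default_rng(42)
        v = rng.uniform(2.0, 24.0, 30)
        w = rng.uniform(-4.0, 12.0, 30)
        states = np.stack([v, w], axis=1)
        fired, _, _ = classify_states(pwl2d, states, **FAST)
        assert np.array_equal(fired, line.fires(states))


class TestTraceManifold:
    def test_2d_stable_manifold_is_the_line(self, pwl2d):
        saddle = next(e for e in find_equilibria(pwl2d, 0.0) if e.is_saddle)
        sb = trace_manifold(pwl2d, saddle, which="stable", sign=-1, horizon=60.0)
        pts = sb.points
        mid = pts[(pts[:, 0] > 2.0) & (pts[:, 0] < 24.0)]
        slope, _ = np.polyfit(mid[:, 0], mid[:, 1], 1)
        assert slope == pytest.approx(K_THETA, abs=1e-6)

    def test_2d_manifold_continues_into_hyperpolarized_region(self, pwl2d):
        saddle = next(e for e in find_equilibria(pwl2d, 0.0) if e.is_saddle)
        sb = trace_manifold(pwl2d, saddle, which="stable", sign=-1, horizon=200.0)
        # the winding branch around rest reaches hyperpolarized voltages
        assert sb.points[:, 0].min() < -5.0

    def test_boltzmann_saddle_branches(self, boltzmann):
        saddle = next(
            e for e in find_equilibria(boltzmann, 0.62) if e.is_saddle
        )
        node = max(find_equilibria(boltzmann, 0.62), key=lambda e: e.v)
        # the stable eigenvalue is weak (~ -0.087): give the backward flow
        # a noticeable seed offset and a long horizon so both branches unfold
        kw = dict(horizon=250.0, i_e=0.62, delta=1e-4, bbox=(-6.0, 6.0))
        left = trace_manifold(boltzmann, saddle, "stable", sign=-1, **kw)
        right = trace_manifold(boltzmann, saddle, "stable", sign=+1, **kw)
        branches = sorted((left, right), key=lambda b: b.points[-1, 0])
        # one branch escapes toward large negative v ...
        assert branches[0].points[:, 0].min() < -2.0
        # ... the other connects back toward the unstable node
        d_node = np.linalg.norm(branches[1].points - node.state, axis=1)
        assert d_node.min() < 0.1

    def test_seed_offset_continuity(self, pwl2d):
        saddle = next(e for e in find_equilibria(pwl2d, 0.0) if e.is_saddle)
        a = trace_manifold(pwl2d, saddle, "stable", -1, horizon=30.0, delta=1e-5)
        b = trace_manifold(pwl2d, saddle, "stable", -1, horizon=30.0, delta=1e-6)
        n = min(len(a.points), len(b.points))
        assert np.abs(a.points[:n] - b.points[:n]).max() < 10 * 1e-5


class TestPWL3DPlane:
    def test_spanning_eigenvalues_match_cubic_oracle(self, pwl3d):
        plane = pwl3d_separatrix(pwl3d, 0.0)
        roots = np.sort(np.roots([1.0, -0.65, -0.115, 0.002]).real)
        assert plane.dominant_eigenvalue == pytest.approx(roots[2], rel=1e-9)
        assert sorted(plane.spanning_eigenvalues) == pytest.approx(
            list(roots[:2]), rel=1e-9
        )

    def test_plane_contains_middle_equilibrium(self, pwl3d):
        plane = pwl3d_separatrix(pwl3d, 0.0)
        eq = next(e for e in find_equilibria(pwl3d, 0.0) if e.region == "middle")
        assert eq.v == pytest.approx(-21.75, rel=1e-12)
        assert abs(plane.signed_distance(eq.state)) < 1e-10

    def test_normal_orthogonal_to_spanning_vectors(self, pwl3d):
        plane = pwl3d_separatrix(pwl3d, 0.0)
        assert np.abs(plane.normal @ plane.spanning_eigenvectors).max() < 1e-10

    def test_on_plane_trajectory_stays_on_plane(self, pwl3d):
        plane = pwl3d_separatrix(pwl3d, 0.0)
        q = _middle_plane_point(plane, v_target=10.0)
        traj = integrate(pwl3d, q, t_end=10.0, dt=0.01)
        in_middle = (traj.states[:, 0] >= 1.5) & (traj.states[:, 0] < 50.0)
        d = np.abs(plane.signed_distance(traj.states[in_middle]))
        assert d.max() < 1e-6

    def test_paired_starts_straddle_the_plane(self, pwl3d):
        plane = pwl3d_separatrix(pwl3d, 0.0)
        q = _middle_plane_point(plane, v_target=10.0)
        starts = np.stack(
            [q + 1e-3 * plane.dominant_eigenvector, q - 1e-3 * plane.dominant_eigenvector]
        )
        fired, _, _ = classify_states(pwl3d, starts, **FAST)
        assert plane.fires(starts[0]) != plane.fires(starts[1])
        assert fired[0] != fired[1]
        assert fired[0] == plane.fires(starts[0])


def _middle_plane_point(plane, v_target):
    d = plane.spanning_eigenvectors.sum(axis=1)
    alpha = (v_target - plane.point[0]) / d[0]
    return plane.point + alpha * d


class TestOrientation:
    def test_rest_on_non_firing_side_everywhere(self, qif, pwl2d, pwl3d):
        assert not qif_threshold(qif, 0.0).fires(qif.v_r)
        assert not pwl2d_separatrix(pwl2d, 0.0).fires([0.0, 0.0])
        assert not pwl3d_separatrix(pwl3d, 0.0).fires(np.zeros(3))

    def test_separatrix_for_dispatch(self, qif, pwl2d, pwl3d, fhn):
        assert separatrix_for(qif).theta == qif.v_t
        assert separatrix_for(pwl2d).k_theta == pytest.approx(K_THETA)
        assert separatrix_for(pwl3d).firing_side in (-1, 1)
        with pytest.raises(SepxError, match="no analytic separatrix"):
            separatrix_for(fhn)


class TestBisectBoundary:
    def test_2d_horizontal_ray_hits_line(self, pwl2d):
        boundary = bisect_boundary(
            pwl2d,
            None,
            anchor=[0.0, 0.0],
            direction=[1.0, 0.0],
            bracket=(2.0, 15.0),
            tol=1e-6,
            **FAST,
        )
        assert boundary[0] == pytest.approx(-B_THETA / K_THETA, abs=1e-4)

    def test_tolerance_contract(self, pwl2d):
        kw = dict(anchor=[0.0, 0.0], direction=[1.0, 0.0], bracket=(2.0, 15.0))
        a = bisect_boundary(pwl2d, None, tol=1e-3, **kw, **FAST)
        b = bisect_boundary(pwl2d, None, tol=5e-4, **kw, **FAST)
        assert abs(a[0] - b[0]) < 1e-3

    def test_qif_dc_boundary_equals_threshold_point(self, qif):
        classifier = make_classifier(qif, i_e=50.0, t_end=40.0, dt=0.005)
        boundary = bisect_boundary(
            qif, classifier, anchor=[0.0], direction=[1.0],
            bracket=(5.0, 35.0), tol=1e-5,
        )
        assert boundary[0] == pytest.approx(qif_threshold(qif, 50.0).theta, abs=1e-4)

    def test_no_flip_raises(self, pwl2d):
        with pytest.raises(BracketError):
            bisect_boundary(
                pwl2d, None, anchor=[0.0, 0.0], direction=[1.0, 0.0],
                bracket=(5.0, 10.0), **FAST,
            )
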