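"""Integrator: RK4 accuracy, protocols, clamping, QIF reset, spike abort."""

import numpy as np
import pytest

from sepx import (
    StimulusProtocol,
    classify_ap,
    get_model,
    integrate,
    linear_region_solution,
    rest_state,
)
from sepx.dynamics import Segment, abort_by_hyperpolarization_demo, evolve_batch
from sepx.exceptions import ConfigError
from sepx.models import resting_equilibrium

from conftest import FAST


class TestRK4Accuracy:
    def test_matches_linear_region_closed_form(self, pwl2d):
        """Middle-region flow vs matrix-exponential solution (dt = 1e-3)."""
        x0 = np.array([5.0, 2.0])
        traj = integrate(pwl2d, x0, t_end=1.0, dt=1e-3)
        exact = linear_region_solution(pwl2d, x0, "middle", 1.0)
        assert np.abs(traj.states[-1] - exact).max() < 1e-6
        # both directions: finer RK4 pins the closed form to 1e-8
        fine = integrate(pwl2d, x0, t_end=0.5, dt=1e-4)
        exact05 = linear_region_solution(pwl2d, x0, "middle", 0.5)
        assert np.abs(fine.states[-1] - exact05).max() < 1e-8

    def test_closed_form_identity_and_fixed_point(self, pwl2d):
        x0 = np.array([5.0, 2.0])
        np.testing.assert_allclose(
            linear_region_solution(pwl2d, x0, "middle", 0.0), x0, atol=1e-12
        )
        saddle = np.array([30.0, 13.5])  # middle-segment fixed point
        np.testing.assert_allclose(
            linear_region_solution(pwl2d, saddle, "middle", 3.0), saddle, atol=1e-9
        )

    def test_3d_region_solution_matches_rk4(self, pwl3d):
        x0 = np.array([10.0, 1.0, 2.0])
        traj = integrate(pwl3d, x0, t_end=0.5, dt=1e-3)
        exact = linear_region_solution(pwl3d, x0, "middle", 0.5)
        assert np.abs(traj.states[-1] - exact).max() < 1e-6

    def test_empirical_convergence_order(self, fhn):
        """Halving dt shrinks the endpoint error ~16x (order >= 3.5)."""
        x0 = np.array([0.5, 0.0])
        ref = integrate(fhn, x0, t_end=2.0, dt=1e-4).states[-1]
        errs = []
        for dt in (0.04, 0.02, 0.01):
            end = integrate(fhn, x0, t_end=2.0, dt=dt).states[-1]
            errs.append(np.abs(end - ref).max())
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert orders.min() >= 3.5


class TestProtocols:
    def test_equilibrium_stays_put(self, pwl2d, fhn):
        for model in (pwl2d, fhn):
            eq = resting_equilibrium(model).state
            traj = integrate(model, eq, t_end=10.0, dt=0.01)
            assert np.abs(traj.states[-1] - eq).max() < 1e-8 * 10.0

    def test_impulse_is_exact_voltage_jump(self, pwl2d):
        traj = integrate(
            pwl2d, [0.0, 0.0], StimulusProtocol.impulse(q=3.0), t_end=0.1, dt=0.01
        )
        np.testing.assert_allclose(traj.states[0], [3.0, 0.0], atol=1e-14)

    def test_narrow_rectangle_converges_to_impulse(self, pwl2d):
        """The rectangular realisation approaches the exact jump as the
        pulse narrows (first order in the width)."""
        exact = integrate(
            pwl2d, [0.0, 0.0], StimulusProtocol.impulse(q=3.0), t_end=2.0, dt=1e-4
        ).states[-1]
        errs = []
        for width in (0.08, 0.02):  # widths well above dt, so the edge
            approx = integrate(      # error of the discontinuity stays small
                pwl2d,
                [0.0, 0.0],
                StimulusProtocol.impulse(q=3.0, width=width),
                t_end=2.0,
                dt=1e-4,
            ).states[-1]
            errs.append(np.abs(exact - approx).max())
        assert errs[1] < errs[0] / 2.0
        assert errs[1] < 0.05

    def test_clamp_holds_voltage_exactly(self, hh, hh_rest):
        traj = integrate(
            hh, hh_rest, StimulusProtocol.clamp(-40.0, 5.0), t_end=5.0, dt=0.01
        )
        held = traj.states[traj.times < 5.0, 0]
        assert np.all(held == -40.0)  # machine-exact pin
        assert any(k == "clamp_release" for _, k in traj.events)

    def test_overlapping_segments_rejected(self):
        p = StimulusProtocol(
            [Segment("dc", 0.0, 5.0, amp=1.0), Segment("step", 4.0, 6.0, amp=1.0)]
        )
        with pytest.raises(ConfigError, match="overlap"):
            p.validate()

    def test_clamp_after_current_rejected(self):
        p = StimulusProtocol(
            [Segment("step", 0.0, 2.0, amp=1.0), Segment("clamp", 3.0, 5.0, v_c=1.0)]
        )
        with pytest.raises(ConfigError, match="clamp"):
            p.validate()

    def test_nonpositive_dt_rejected(self, pwl2d):
        with pytest.raises(ConfigError, match="dt"):
            integrate(pwl2d, [0.0, 0.0], dt=0.0)


class TestQIFReset:
    def test_spike_peak_then_reset_to_v_reset(self, qif):
        traj = integrate(qif, [qif.v_t + 1.0], t_end=5.0, dt=1e-3)
        kinds = [k for _, k in traj.events]
        assert "spike_peak" in kinds and "reset" in kinds
        i_reset = next(i for i, (_, k) in enumerate(traj.events) if k == "reset")
        t_reset = traj.events[i_reset][0]
        idx = int(round(t_reset / 1e-3))
        assert traj.states[idx, 0] == qif.v_reset

    def test_below_unstable_root_never_fires(self, qif):
        traj = integrate(qif, [qif.v_t - 1e-3], t_end=50.0, dt=1e-2)
        is_ap, v_max, _ = classify_ap(traj, qif)
        assert not is_ap
        assert v_max < qif.v_t

    def test_above_root_fires(self, qif):
        traj = integrate(qif, [qif.v_t + 1e-3], t_end=50.0, dt=1e-2)
        is_ap, _, _ = classify_ap(traj, qif)
        assert is_ap


class TestClassify:
    def test_hh_rest_is_quiet(self, hh, hh_rest):
        traj = integrate(hh, hh_rest, t_end=30.0, dt=0.01)
        is_ap, v_max, _ = classify_ap(traj, hh)
        assert not is_ap
        assert v_max == pytest.approx(hh_rest[0], abs=1e-3)

    def test_batch_matches_single(self, pwl2d):
        states = np.array([[10.0, 0.0], [3.0, 0.0], [-5.0, 0.0]])
        out = evolve_batch(pwl2d, states, **FAST)
        singles = [
            classify_ap(integrate(pwl2d, s, **FAST), pwl2d)[0] for s in states
        ]
        assert list(out["fired"]) == singles

    def test_rest_state_is_stationary(self, pwl2d):
        rest = rest_state(pwl2d)
        np.testing.assert_allclose(rest, [0.0, 0.0], atol=1e-10)


class TestSpikeAbort:
    ABORT = dict(t_end=25.0, dt=2e-3)

    def test_zero_amplitude_keeps_baseline_spike(self, qif):
        assert abort_by_hyperpolarization_demo(
            qif, t_cross=0.01, I_hyp=0.0, dur=1.0, **self.ABORT
        )

    def test_strong_long_hyperpolarization_aborts(self, qif):
        assert not abort_by_hyperpolarization_demo(
            qif, t_cross=0.01, I_hyp=1e4, dur=5.0, **self.ABORT
        )

    def test_single_sign_change_over_amplitude_grid(self, qif):
        fired = [
            abort_by_hyperpolarization_demo(
                qif, t_cross=0.01, I_hyp=a, dur=2.0, **self.ABORT
            )
            for a in np.linspace(0.0, 400.0, 21)
        ]
        flips = np.diff(np.asarray(fired).astype(int))
        assert np.count_nonzero(flips) == 1
        assert fired[0] and not fired[-1]
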