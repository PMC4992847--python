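"""Model zoo: right-hand sides, equilibria, Jacobians, HH rate functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepx import get_model, hh_rates, piecewise_f
from sepx.exceptions import (
    DimensionMismatchError,
    FixtureValidationError,
    NonFiniteStateError,
    RegionAmbiguityError,
)
from sepx.models import (
    MODEL_NAMES,
    find_equilibria,
    jacobian_fd,
    piecewise_region,
    resting_equilibrium,
)


class TestEvalRhs:
    def test_qif_rest_is_root(self, qif):
        assert qif.rhs([qif.v_r], 0.0)[0] == 0.0

    def test_pwl2d_origin_is_rest(self, pwl2d):
        # hand evaluation: f(0) = b_l = 0 and w-nullcline passes through 0
        np.testing.assert_array_equal(pwl2d.rhs([0.0, 0.0], 0.0), [0.0, 0.0])

    def test_hh_settled_rest_has_tiny_derivatives(self, hh, hh_rest):
        assert np.abs(hh.rhs(hh_rest, 0.0)).max() < 1e-6

    def test_dimension_mismatch_raises(self, pwl2d):
        with pytest.raises(DimensionMismatchError):
            pwl2d.rhs([0.0, 0.0, 0.0], 0.0)

    def test_nonfinite_state_raises(self, pwl2d):
        with pytest.raises(NonFiniteStateError):
            pwl2d.rhs([np.nan, 0.0], 0.0)

    def test_rhs_deterministic(self, hh, hh_rest):
        a = hh.rhs(hh_rest + 1.0, 3.0)
        b = hh.rhs(hh_rest + 1.0, 3.0)
        np.testing.assert_array_equal(a, b)


class TestPiecewiseF:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (0.0, 0.0),  # left segment, b_l = 0
            (1.5, -0.75),  # breakpoint belongs to the middle segment
            (25.0, 11.0),  # right segment: -0.25*25 + 17.25
            (-4.0, 2.0),  # left: -0.5 * -4
            (10.0, 3.5),  # middle: 0.5*10 - 1.5
        ],
    )
    def test_segment_values(self, pwl2d, v, expected):
        assert piecewise_f(pwl2d.f, v) == pytest.approx(expected, abs=1e-12)

    @given(v=st.floats(-100, 100, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_every_voltage_in_exactly_one_region(self, v):
        plv = get_model("pwl2d").f
        region = piecewise_region(plv, v)
        lo, hi = plv.region_interval(region)
        assert lo <= v < hi


class TestEquilibria:
    def test_pwl2d_three_fixed_points(self, pwl2d):
        eqs = sorted(find_equilibria(pwl2d, 0.0), key=lambda e: e.v)
        assert len(eqs) == 3
        rest, mid, saddle = eqs
        assert rest.v == pytest.approx(0.0, abs=1e-12)
        assert (rest.region, rest.reality, rest.stability) == (
            "left", "real", "stable spiral",
        )
        # right-segment fixed point sits in the middle region: virtual
        assert mid.v == pytest.approx(17.25 / 0.7, rel=1e-12)
        assert (mid.region, mid.reality, mid.stability) == (
            "right", "virtual", "stable spiral",
        )
        # middle-segment fixed point sits in the right region: virtual saddle
        assert saddle.v == pytest.approx(30.0, rel=1e-12)
        assert (saddle.region, saddle.reality) == ("middle", "virtual")
        assert saddle.is_saddle

    def test_segment_fixed_points_solve_their_equations_exactly(self, pwl2d, pwl3d):
        for model in (pwl2d, pwl3d):
            for eq in find_equilibria(model, 0.0):
                A, c = model.region_affine(eq.region, 0.0)
                assert np.abs(A @ eq.state + c).max() < 1e-12

    def test_qif_roots(self, qif):
        eqs = sorted(find_equilibria(qif, 0.0), key=lambda e: e.v)
        assert [e.v for e in eqs] == pytest.approx([qif.v_r, qif.v_t])
        assert eqs[0].stability == "stable point"
        assert eqs[1].stability == "unstable point"

    def test_boltzmann_fhn_type1_portrait(self, boltzmann):
        eqs = sorted(find_equilibria(boltzmann, 0.62), key=lambda e: e.v)
        assert len(eqs) == 3
        assert eqs[0].stability.startswith("stable")
        assert eqs[1].is_saddle
        assert eqs[2].stability == "unstable node"

    def test_classic_fhn_single_equilibrium(self, fhn):
        eqs = find_equilibria(fhn, 0.0)
        assert len(eqs) == 1
        assert eqs[0].stability.startswith("stable")

    def test_resting_equilibrium_is_origin_for_pwl2d(self, pwl2d):
        assert resting_equilibrium(pwl2d).v == pytest.approx(0.0, abs=1e-12)


class TestJacobian:
    def test_pwl2d_middle_matrix(self, pwl2d):
        J = pwl2d.jacobian([10.0, 0.0])
        np.testing.assert_allclose(J, [[0.5, -1.0], [0.09, -0.2]], atol=1e-15)
        assert np.trace(J) == pytest.approx(0.3)
        assert np.linalg.det(J) == pytest.approx(-0.01)  # saddle

    def test_qif_scalar_derivative_stable_at_rest(self, qif):
        assert qif.jacobian([qif.v_r])[0, 0] == pytest.approx(qif.v_r - qif.v_t)

    def test_breakpoint_needs_region(self, pwl2d):
        with pytest.raises(RegionAmbiguityError):
            pwl2d.jacobian([1.5, 0.0])
        J = pwl2d.jacobian([1.5, 0.0], region="left")
        assert J[0, 0] == pytest.approx(-0.5)

    @pytest.mark.parametrize("name", ["qif", "fhn", "boltzmann-fhn", "fhn3d", "hh"])
    def test_analytic_matches_finite_difference(self, name):
        model = get_model(name)
        state = model.rest_guess() + 0.37 * np.arange(1, model.dim + 1) / model.dim
        if name == "hh":
            state[1:] = np.clip(state[1:], 0.05, 0.95)
        J = model.jacobian(state, 0.1)
        Jfd = jacobian_fd(model, state, 0.1)
        np.testing.assert_allclose(J, Jfd, rtol=2e-6, atol=1e-7)

    def test_eigen_classification_matches_trace_det(self, pwl2d):
        for region in ("left", "middle", "right"):
            A = pwl2d.region_jacobian(region)
            tr, det = np.trace(A), np.linalg.det(A)
            lam = np.linalg.eigvals(A)
            if det < 0:
                assert lam.real.min() < 0 < lam.real.max()  # saddle
            elif tr < 0:
                assert np.all(lam.real < 0)  # stable


class TestHHRates:
    def test_continuous_no_nan_on_working_range(self):
        V = np.arange(-120.0, 60.0 + 1e-9, 0.1)
        r = hh_rates(V)
        for key in ("alpha", "beta", "x_inf", "tau_x"):
            assert np.all(np.isfinite(r[key])), key
        assert np.all(r["alpha"] > 0) and np.all(r["beta"] > 0)
        assert np.all((r["x_inf"] > 0) & (r["x_inf"] < 1))
        assert np.all(r["tau_x"] > 0)

    @pytest.mark.parametrize("V_sing, idx, limit", [(-40.0, 0, 1.0), (-55.0, 2, 0.1)])
    def test_removable_singularities_filled_by_limit(self, V_sing, idx, limit):
        # L'Hopital: x/(1 - e^(-x/10)) -> 10 as x -> 0, so alpha_m -> 1.0
        # and alpha_n -> 0.1 at their singular voltages
        assert hh_rates(V_sing)["alpha"][idx] == pytest.approx(limit, abs=1e-12)
        # continuity: symmetric average cancels the linear term
        near = 0.5 * (
            hh_rates(V_sing + 1e-6)["alpha"][idx]
            + hh_rates(V_sing - 1e-6)["alpha"][idx]
        )
        assert hh_rates(V_sing)["alpha"][idx] == pytest.approx(near, abs=1e-9)

    def test_x_inf_matches_settled_gating(self, hh, hh_rest):
        np.testing.assert_allclose(
            hh_rates(hh_rest[0])["x_inf"], hh_rest[1:], atol=1e-6
        )


class TestAdaptationForm:
    @given(
        v=st.floats(-80, 40, allow_nan=False),
        frac=st.floats(0.0, 2.0),
        seed=st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_gating_rate_has_sign_of_gap(self, v, frac, seed):
        """dx/dt always relaxes x toward x_inf(v) (monotone adaptation)."""
        name = ["pwl2d", "pwl3d", "fhn", "hh"][seed]
        model = get_model(name)
        if name == "hh":
            v = np.clip(v, -100, 50)
        xinf = np.atleast_1d(model.gating_inf(v))
        x = xinf * frac
        state = np.concatenate([[v], x])
        dx = model.rhs(state, 0.0)[1:]
        gap = xinf - x
        assert np.all(np.sign(dx) == np.sign(gap))


class TestRegistry:
    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            get_model("izhikevich")

    def test_unknown_parameter(self):
        with pytest.raises(ValueError, match="no parameter"):
            get_model("qif", v_half=3.0)

    def test_qif_ordering_invariant_enforced(self):
        with pytest.raises(FixtureValidationError):
            get_model("qif", v_peak=10.0)  # v_peak < v_t

    def test_piecewise_override_routed_into_nullcline(self):
        m = get_model("pwl2d", k_m=0.6)
        assert m.f.k_m == 0.6
        assert m.params()["k_m"] == 0.6

    def test_boltzmann_fixture_validation_rejects_broken_portrait(self):
        with pytest.raises(FixtureValidationError):
            get_model("boltzmann-fhn", b=5.0)  # sigmoid off the middle branch

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_params_round_trip(self, name):
        m = get_model(name)
        again = get_model(name, **{
            k: v for k, v in m.params().items()
        })
        assert again.params() == m.params()
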