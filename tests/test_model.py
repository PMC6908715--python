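"""Vector fields, Jacobian, integrator and the heart-rate law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvamecg.errors import (DivergedTrajectoryError, DomainError,
                            InvalidStateError)
from bvamecg.model import (DEFAULT_X0, ModelParams, gamma_from_hr,
                           hr_from_gamma, integrate, jacobian4, rhs4, rhs6)

finite_state = st.lists(
    st.floats(min_value=-3.0, max_value=3.0, allow_nan=False), min_size=4,
    max_size=4)


class TestVectorFields:
    def test_origin_is_equilibrium(self, params_h3):
        assert np.all(rhs4(np.zeros(4), params_h3) == 0)
        assert np.all(rhs6(np.zeros(6), params_h3) == 0)

    def test_rhs4_kick_on_third_component(self, params_h3):
        # direct substitution: only the second oscillator pair responds
        np.testing.assert_allclose(rhs4([0, 0, 0.1, 0], params_h3),
                                   [0.0, 0.0, 0.1, 0.3], rtol=1e-14)

    def test_rhs6_kick_on_middle_node(self, params_h3):
        out = rhs6([0, 0, 0.1, 0, 0, 0], params_h3)
        np.testing.assert_allclose(out, [0, 0, 0.1, 0.3, 0, 0], atol=0)

    @settings(derandomize=True, max_examples=25)
    @given(state=finite_state)
    def test_symmetric_coupling_cancels(self, state):
        """With x2 == x4 both coupling terms vanish: rhs is beta-independent."""
        x = np.array(state)
        x[3] = x[1]
        p1 = ModelParams(H=5.0, beta=4.0)
        p2 = ModelParams(H=5.0, beta=9.0)
        np.testing.assert_allclose(rhs4(x, p1), rhs4(x, p2), rtol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(state=st.lists(st.floats(-2, 2, allow_nan=False), min_size=6,
                          max_size=6))
    def test_rhs6_boundary_exchange_symmetry(self, state):
        """Swapping the two boundary oscillators swaps their rates."""
        p = ModelParams(H=4.0)
        x = np.array(state)
        swapped = x[[4, 5, 2, 3, 0, 1]]
        np.testing.assert_allclose(rhs6(swapped, p),
                                   rhs6(x, p)[[4, 5, 2, 3, 0, 1]],
                                   rtol=1e-12, atol=1e-14)

    def test_nonfinite_state_rejected(self, params_h3):
        with pytest.raises(InvalidStateError):
            rhs4([np.nan, 0, 0, 0], params_h3)
        with pytest.raises(InvalidStateError):
            rhs6([0, 0, np.inf, 0, 0, 0], params_h3)


class TestJacobian:
    def test_hand_computed_at_origin(self):
        p = ModelParams(H=10.0, beta=4.0)
        expected = np.array([[1, -1, 0, 0],
                             [10, -7, 0, 4],
                             [0, 0, 1, -1],
                             [0, 8, 10, -11]], dtype=float)
        np.testing.assert_allclose(jacobian4(np.zeros(4), p), expected)

    @settings(derandomize=True, max_examples=30)
    @given(state=finite_state, H=st.floats(1.0, 15.0))
    def test_matches_central_finite_differences(self, state, H):
        p = ModelParams(H=H)
        x = np.array(state)
        J = jacobian4(x, p)
        Jfd = np.empty((4, 4))
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            Jfd[:, j] = (rhs4(x + e, p) - rhs4(x - e, p)) / (2 * h)
        np.testing.assert_allclose(J, Jfd, rtol=1e-6, atol=1e-5)

    def test_trace_at_origin(self):
        for beta in (1.0, 4.0, 7.5):
            p = ModelParams(H=12.0, beta=beta)
            assert np.isclose(np.trace(jacobian4(np.zeros(4), p)),
                              -4.0 - 3.0 * beta)


class TestIntegrator:
    def test_equilibrium_is_fixed_point(self, params_h3):
        traj = integrate(rhs4, np.zeros(4), 0.005, 100, params_h3)
        assert np.max(np.abs(traj.states)) == 0.0

    def test_fourth_order_convergence_on_linear_ode(self):
        """Global error against exp(-t) shrinks ~16x when dt is halved."""
        decay = lambda x, params: -x
        p = ModelParams(H=3.0)
        errors = []
        for dt in (0.1, 0.05):
            n = int(round(1.0 / dt))
            traj = integrate(decay, [1.0], dt, n, p)
            errors.append(abs(traj.states[-1, 0] - np.exp(-1.0)))
        ratio = errors[0] / errors[1]
        assert 12.0 < ratio < 20.0

    def test_time_rescaling_equivalence(self):
        """(gamma_t, dt) and (1, gamma_t*dt) produce the same samples."""
        fast = ModelParams(H=3.0, gamma_t=7.0)
        slow = ModelParams(H=3.0, gamma_t=1.0)
        t1 = integrate(rhs4, DEFAULT_X0, 0.001, 4000, fast)
        t2 = integrate(rhs4, DEFAULT_X0, 0.007, 4000, slow)
        np.testing.assert_allclose(t1.states, t2.states, rtol=1e-9,
                                   atol=1e-10)

    def test_reduction_equivalence_short(self, params_h3):
        """Symmetric 6-component start reproduces the 4-component flow."""
        x6 = np.array([0.0, 0.0, 0.1, 0.0, 0.0, 0.0])
        t6 = integrate(rhs6, x6, 0.005, 10_000, params_h3)
        t4 = integrate(rhs4, DEFAULT_X0, 0.005, 10_000, params_h3)
        np.testing.assert_allclose(t6.states[:, :4], t4.states, atol=1e-10)
        # the boundary oscillators stay locked to each other
        np.testing.assert_allclose(t6.states[:, 4], t6.states[:, 0],
                                   atol=1e-12)

    def test_divergence_guard(self):
        with pytest.raises(DivergedTrajectoryError):
            integrate(rhs4, [50.0, 50.0, 50.0, 50.0], 0.1, 1000,
                      ModelParams(H=20.0))

    def test_invalid_steps(self, params_h3):
        with pytest.raises(DomainError):
            integrate(rhs4, DEFAULT_X0, -0.005, 10, params_h3)
        with pytest.raises(DomainError):
            integrate(rhs4, DEFAULT_X0, 0.005, 0, params_h3)


class TestHeartRateLaw:
    def test_values(self):
        assert np.isclose(gamma_from_hr(60.0), 5.21486)
        assert np.isclose(hr_from_gamma(7.0), 80.276, atol=5e-3)
        assert np.isclose(hr_from_gamma(17.0), 193.861, atol=5e-3)

    @settings(derandomize=True, max_examples=30)
    @given(hr=st.floats(1.0, 300.0))
    def test_roundtrip_identity(self, hr):
        assert np.isclose(hr_from_gamma(gamma_from_hr(hr)), hr, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            gamma_from_hr(0.5)          # below the root of the affine law
        with pytest.raises(DomainError):
            hr_from_gamma(0.0)


class TestModelParams:
    def test_validation(self):
        with pytest.raises(DomainError):
            ModelParams(H=3.0, C=-1.0)
        with pytest.raises(DomainError):
            ModelParams(H=3.0, beta=0.0)
        with pytest.raises(DomainError):
            ModelParams(H=np.inf)

    def test_h_outside_studied_range_warns(self):
        with pytest.warns(UserWarning):
            ModelParams(H=25.0)
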