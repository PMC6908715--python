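"""Equilibria, cycles, Floquet machinery, Lyapunov exponents, spectra."""

import numpy as np
import pytest

from bvamecg.dynamics import (find_equilibria, find_hopf, find_limit_cycle,
                              largest_lyapunov, lyapunov_scan, monodromy,
                              poincare_section, power_spectrum)
from bvamecg.errors import DomainError, NoCycleError
from bvamecg.model import (DEFAULT_X0, ModelParams, Trajectory, integrate,
                           jacobian4, rhs4)


class TestEquilibria:
    def test_census_contains_origin_and_roots_are_exact(self):
        records = find_equilibria(ModelParams(H=10.0), n_starts=4)
        assert any(np.max(np.abs(r.state)) == 0 for r in records)
        for r in records:
            assert np.max(np.abs(rhs4(r.state, ModelParams(H=10.0)))) < 1e-10

    def test_stable_family_exists_at_high_H(self):
        records = find_equilibria(ModelParams(H=10.0), n_starts=4)
        assert any(r.stable and np.max(np.abs(r.state)) > 1e-6
                   for r in records)

    def test_eigenvalues_come_from_jacobian(self):
        records = find_equilibria(ModelParams(H=12.0), n_starts=3)
        for r in records:
            ev = np.linalg.eigvals(jacobian4(r.state, ModelParams(H=12.0)))
            np.testing.assert_allclose(np.sort_complex(r.eigenvalues),
                                       np.sort_complex(ev), rtol=1e-9)


class TestHopf:
    def test_location_is_gamma_invariant(self):
        """Uniform time rescaling cannot move the stability boundary."""
        bp = find_hopf(ModelParams(H=3.0, gamma_t=3.0))
        assert abs(bp.H_star - 8.779267) < 1e-3
        # witness is a conjugate pair on the imaginary axis
        assert abs(bp.witness[0].real) < 1e-5 * 3.0
        assert abs(bp.witness[0].imag) > 1.0


class TestCycles:
    def test_attractor_cycle_at_h7(self, cycle_h7):
        assert 1.15 < cycle_h7.period < 1.25
        assert cycle_h7.residual < 1e-10
        trivial = cycle_h7.multipliers[
            np.argmin(np.abs(cycle_h7.multipliers - 1))]
        assert abs(trivial - 1.0) < 1e-3
        assert cycle_h7.stable
        assert np.max(np.abs(cycle_h7.nontrivial_multipliers())) < 1.0

    def test_monodromy_recomputation_matches(self, cycle_h7, params_h7):
        mult = monodromy(cycle_h7, params_h7)
        np.testing.assert_allclose(
            np.sort(np.abs(mult)), np.sort(np.abs(cycle_h7.multipliers)),
            rtol=1e-6, atol=1e-9)

    def test_abel_liouville_identity(self, cycle_h7, params_h7):
        """det(monodromy) equals exp of the cycle-integrated Jacobian trace."""
        n = 4000
        h = cycle_h7.period / n
        traj = integrate(rhs4, cycle_h7.anchor, h, n, params_h7)
        traces = np.array([np.trace(jacobian4(s, params_h7))
                           for s in traj.states])
        integral = np.trapezoid(traces, dx=h)
        prod = np.prod(cycle_h7.multipliers).real
        assert abs(prod - np.exp(integral)) < 1e-4 * abs(np.exp(integral))

    def test_shooting_rejects_hopeless_guess(self, params_h7):
        with pytest.raises(NoCycleError):
            find_limit_cycle(params_h7, [40.0, 0.0, 40.0, 40.0], 0.6,
                             max_iter=5)


class TestPoincare:
    def test_circular_orbit_one_point_per_period(self):
        t = np.arange(0, 10.55, 0.01)
        states = np.column_stack([np.sin(2 * np.pi * t),
                                  np.cos(2 * np.pi * t)])
        traj = Trajectory(times=t, states=states,
                          params=ModelParams(H=3.0), dt=0.01)
        pts = poincare_section(traj, plane=(0, 0.0, +1))
        assert len(pts) == 10
        assert np.max(np.abs(pts[:, 0])) < 1e-9          # on the plane
        np.testing.assert_allclose(pts[:, 1], 1.0, atol=1e-3)

    def test_no_crossings_gives_empty(self):
        t = np.arange(0, 1.0, 0.01)
        states = np.column_stack([np.full_like(t, 2.0), t])
        traj = Trajectory(times=t, states=states,
                          params=ModelParams(H=3.0), dt=0.01)
        assert len(poincare_section(traj, plane=(0, 0.0, +1))) == 0

    def test_direction_filtering(self):
        t = np.arange(0, 2.05, 0.01)
        states = np.column_stack([np.sin(2 * np.pi * t),
                                  np.cos(2 * np.pi * t)])
        traj = Trajectory(times=t, states=states,
                          params=ModelParams(H=3.0), dt=0.01)
        up = poincare_section(traj, plane=(0, 0.0, +1))
        down = poincare_section(traj, plane=(0, 0.0, -1))
        assert len(up) == len(down) == 2
        np.testing.assert_allclose(up[:, 1], 1.0, atol=1e-3)
        np.testing.assert_allclose(down[:, 1], -1.0, atol=1e-3)


class TestLyapunov:
    def test_stable_equilibrium_matches_eigenvalue_oracle(self):
        """At H=10 the exponent equals the leading eigenvalue of the
        attracting equilibrium."""
        p = ModelParams(H=10.0)
        lam = largest_lyapunov(p, t_transient=500.0, t_total=2500.0)
        traj = integrate(rhs4, DEFAULT_X0, 0.005, 100_000, p)
        from bvamecg.dynamics import _newton_equilibrium
        eq = _newton_equilibrium(traj.states[-1], p)
        lead = np.max(np.linalg.eigvals(jacobian4(eq, p)).real)
        assert lam < 0
        assert abs(lam - lead) < 0.1 * abs(lead)

    def test_gamma_rescales_exponent(self):
        lam1 = largest_lyapunov(ModelParams(H=10.0), t_total=1500.0)
        lam2 = largest_lyapunov(ModelParams(H=10.0, gamma_t=2.0),
                                t_total=750.0, t_transient=250.0,
                                renorm_dt=0.5, dt=0.0025)
        assert abs(lam2 - 2.0 * lam1) < 0.05 * abs(2.0 * lam1)

    def test_scan_grid_and_periodic_window(self):
        # long transient: chaotic saddles delay settling onto the stable
        # cycles that exist throughout this window
        scan = lyapunov_scan(ModelParams(H=2.76), (2.76, 2.80), step=0.009,
                             t_transient=1500.0, t_total=5500.0)
        assert len(scan.H_values) == int(np.floor(0.04 / 0.009)) + 1
        assert np.all(scan.lambda_max < 0.02)   # stable cycles above TR

    def test_bad_time_budget(self):
        with pytest.raises(DomainError):
            largest_lyapunov(ModelParams(H=7.0), t_transient=100.0,
                             t_total=50.0)


class TestPowerSpectrum:
    def test_pure_tone_peak_within_one_bin(self):
        fs, f0 = 100.0, 5.0
        t = np.arange(1000) / fs
        spec = power_spectrum(np.sin(2 * np.pi * f0 * t), fs)
        df = fs / 1024
        assert abs(spec.peaks[0] - f0) <= df

    def test_windowed_parseval_identity(self, rng):
        x = rng.normal(size=777)
        spec = power_spectrum(x, 50.0)
        xw = (x - x.mean()) * np.hanning(len(x))
        assert np.isclose(spec.power.sum(), np.sum(xw ** 2), rtol=1e-9)
        assert np.all(spec.power >= 0)

    def test_input_validation(self):
        with pytest.raises(DomainError):
            power_spectrum([1.0], 10.0)
        with pytest.raises(DomainError):
            power_spectrum([1.0, 2.0, 3.0], 0.0)
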