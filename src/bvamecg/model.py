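"""Discretized BVAM oscillator chain: vector fields, Jacobian, integrator.

The BVAM (Barrio-Varea-Aragon-Maini) reaction-diffusion system, discretized
on a three-node stencil with zero-flux boundaries, yields three identical
nonlinear oscillators coupled in series through the inhibitor components.
The oscillators map onto the heart's natural pacemakers: the sinoatrial
node, the atrioventricular node and the His-Purkinje complex.  A symmetry
of the chain (the two boundary nodes stay identical when started
identically) reduces the six equations to four.

Fixed kinetic constants eta = 1, a = -1, b = -3 place the single oscillator
in its excitable, oscillatory regime and are substituted directly into the
polynomial right-hand sides.  The remaining knobs are

* ``H``   -- linear cross-activation strength; the control parameter that
  carries the system from stationary states through a Hopf bifurcation,
  period doubling and a torus bifurcation into chaos,
* ``C``   -- ratio of quadratic to cubic nonlinearity (fixed at 1.35 in all
  studied regimes),
* ``beta``-- inter-node coupling, 1/(dx)^2 of the discrete Laplacian,
* ``gamma_t`` -- a uniform time-scale factor multiplying the vector field,
  affine in the heart rate (see :func:`gamma_from_hr`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import DIVERGENCE_THRESHOLD
from .errors import DivergedTrajectoryError, DomainError, InvalidStateError

__all__ = [
    "ModelParams", "Trajectory", "DEFAULT_X0", "DEFAULT_DT",
    "rhs4", "rhs6", "jacobian4", "integrate",
    "gamma_from_hr", "hr_from_gamma",
]

#: Initial state used throughout: a small perturbation of the origin.
DEFAULT_X0 = np.array([0.0, 0.0, 0.1, 0.0])

#: Default fixed integration step (dimensionless time).
DEFAULT_DT = 0.005

# Coefficients of the affine heart-rate/time-scale law.
_HR_SLOPE = 0.08804
_HR_INTERCEPT = -0.06754

# H range explored in the bifurcation study; values outside only warn.
_H_STUDIED = (1.0, 20.0)


@dataclass(frozen=True)
class ModelParams:
    """Dynamical parameters of the oscillator chain.

    All quantities are dimensionless.  ``gamma_t = 1`` keeps the model in
    dimensionless time; physiological seconds are obtained with the
    heart-rate law (:func:`gamma_from_hr`).
    """

    H: float
    C: float = 1.35
    beta: float = 4.0
    gamma_t: float = 1.0

    def __post_init__(self):
        for name in ("H", "C", "beta", "gamma_t"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v!r}")
        if self.C <= 0:
            raise DomainError(f"C must be positive, got {self.C}")
        if self.beta <= 0:
            raise DomainError(f"beta must be positive, got {self.beta}")
        if self.gamma_t <= 0:
            raise DomainError(f"gamma_t must be positive, got {self.gamma_t}")
        if not (_H_STUDIED[0] <= self.H <= _H_STUDIED[1]):
            warnings.warn(
                f"H={self.H} lies outside the studied interval "
                f"[{_H_STUDIED[0]}, {_H_STUDIED[1]}]; dynamics are "
                "uncharacterized there", stacklevel=3)

    def with_H(self, H: float) -> "ModelParams":
        return replace(self, H=H)

    def with_gamma_t(self, gamma_t: float) -> "ModelParams":
        return replace(self, gamma_t=gamma_t)


@dataclass
class Trajectory:
    """Uniformly sampled solution of the 4- or 6-component system.

    ``times`` are seconds when the trajectory was produced with a physical
    ``gamma_t``; with ``gamma_t = 1`` they are dimensionless time.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    dt: float
    x0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.x0 is None:
            self.x0 = self.states[0].copy()
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if steps.min() <= 0 or not np.allclose(
                    steps, self.dt, rtol=1e-9, atol=1e-12):
                raise ValueError("times must increase with constant step dt")

    @property
    def n_components(self) -> int:
        return self.states.shape[1]

    def component(self, i: int) -> np.ndarray:
        return self.states[:, i]


def _check_state(x, dim: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (dim,):
        raise InvalidStateError(f"expected a {dim}-component state, "
                                f"got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"non-finite state component in {x!r}")
    return x


def rhs4(state, params: ModelParams) -> np.ndarray:
    """Time derivative of the reduced four-component system.

    With ``gamma_t = 1`` this is exactly the dimensionless reduced system;
    otherwise every component is scaled by ``gamma_t``.
    """
    x = _check_state(state, 4)
    return _kernels.rhs4(x, params.H, params.C, params.beta, params.gamma_t)


def rhs6(state, params: ModelParams) -> np.ndarray:
    """Time derivative of the full six-component three-oscillator chain."""
    x = _check_state(state, 6)
    return _kernels.rhs6(x, params.H, params.C, params.beta, params.gamma_t)


def jacobian4(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs4` (including the gamma_t factor)."""
    x = _check_state(state, 4)
    return _kernels.jac4(x, params.H, params.C, params.beta, params.gamma_t)


def integrate(rhs, x0, dt: float, n_steps: int,
              params: ModelParams) -> Trajectory:
    """Integrate a vector field with the classical fixed-step RK4 scheme.

    ``rhs`` is normally :func:`rhs4` or :func:`rhs6`, which dispatch to
    compiled sweeps; any other callable ``f(x, params) -> dx/dt`` is
    integrated by a generic Python loop (useful for convergence tests on
    problems with closed-form solutions).

    Raises
    ------
    DivergedTrajectoryError
        if any state component exceeds 1e6 in magnitude.
    """
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    if n_steps < 1:
        raise DomainError(f"n_steps must be >= 1, got {n_steps}")

    if rhs is rhs4 or rhs is rhs6:
        dim = 4 if rhs is rhs4 else 6
        x = _check_state(x0, dim)
        kernel = _kernels.rk4_traj4 if dim == 4 else _kernels.rk4_traj6
        states, ok = kernel(x, params.H, params.C, params.beta,
                            params.gamma_t, dt, n_steps)
        if not ok:
            raise DivergedTrajectoryError(
                f"trajectory exceeded |x| = {DIVERGENCE_THRESHOLD:g} "
                f"(H={params.H})")
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
        states = np.empty((n_steps + 1, x.size))
        states[0] = x
        for i in range(n_steps):
            k1 = np.asarray(rhs(x, params))
            k2 = np.asarray(rhs(x + 0.5 * dt * k1, params))
            k3 = np.asarray(rhs(x + 0.5 * dt * k2, params))
            k4 = np.asarray(rhs(x + dt * k3, params))
            x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            states[i + 1] = x
            if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
                raise DivergedTrajectoryError(
                    f"trajectory exceeded |x| = {DIVERGENCE_THRESHOLD:g}")

    times = dt * np.arange(n_steps + 1)
    return Trajectory(times=times, states=states, params=params, dt=dt,
                      x0=np.asarray(x0, dtype=float))


def gamma_from_hr(hr_bpm: float) -> float:
    """Time-scale factor for a given heart rate (beats/min).

    The factor is affine in the heart rate:
    ``gamma_t = 0.08804 * HR - 0.06754``.  Heart rates at or below the root
    of this line (~0.767 bpm) have no positive time scale.
    """
    g = _HR_SLOPE * hr_bpm + _HR_INTERCEPT
    if g <= 0:
        raise DomainError(
            f"heart rate {hr_bpm} bpm yields non-positive gamma_t = {g}")
    return g


def hr_from_gamma(gamma_t: float) -> float:
    """Heart rate (beats/min) corresponding to a time-scale factor."""
    if gamma_t <= 0:
        raise DomainError(f"gamma_t must be positive, got {gamma_t}")
    return (gamma_t - _HR_INTERCEPT) / _HR_SLOPE
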