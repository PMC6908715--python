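"""Numba-compiled inner loops.

Everything here operates on bare float64 arrays and scalar parameters so the
classical fixed-step RK4 sweeps (trajectories, variational/monodromy flows,
Benettin tangent propagation) run at native speed.  The readable reference
implementations of the vector fields live in :mod:`bvamecg.model`; the unit
tests assert that kernel and reference agree to round-off.

The kinetic constants eta = 1, a = -1, b = -3 of the underlying BVAM
reaction-diffusion kinetics are already substituted into the polynomial
right-hand sides, mirroring how the discretized equations are written.
"""

import numpy as np
from numba import njit

DIVERGENCE_THRESHOLD = 1.0e6


@njit(cache=True)
def rhs4(x, H, C, beta, gamma_t):
    """Right-hand side of the four-component (two-oscillator) system."""
    out = np.empty(4)
    x1, x2, x3, x4 = x[0], x[1], x[2], x[3]
    out[0] = gamma_t * (x1 - x2 - C * x1 * x2 - x1 * x2 * x2)
    out[1] = gamma_t * (H * x1 - 3.0 * x2 + C * x1 * x2 + x1 * x2 * x2
                        + beta * (x4 - x2))
    out[2] = gamma_t * (x3 - x4 - C * x3 * x4 - x3 * x4 * x4)
    out[3] = gamma_t * (H * x3 - 3.0 * x4 + C * x3 * x4 + x3 * x4 * x4
                        + 2.0 * beta * (x2 - x4))
    return out


@njit(cache=True)
def rhs6(x, H, C, beta, gamma_t):
    """Right-hand side of the six-component (three-oscillator chain) system."""
    out = np.empty(6)
    x1, x2, x3, x4, x5, x6 = x[0], x[1], x[2], x[3], x[4], x[5]
    out[0] = gamma_t * (x1 - x2 - C * x1 * x2 - x1 * x2 * x2)
    out[1] = gamma_t * (H * x1 - 3.0 * x2 + C * x1 * x2 + x1 * x2 * x2
                        + beta * (x4 - x2))
    out[2] = gamma_t * (x3 - x4 - C * x3 * x4 - x3 * x4 * x4)
    out[3] = gamma_t * (H * x3 - 3.0 * x4 + C * x3 * x4 + x3 * x4 * x4
                        + beta * (x6 - 2.0 * x4 + x2))
    out[4] = gamma_t * (x5 - x6 - C * x5 * x6 - x5 * x6 * x6)
    out[5] = gamma_t * (H * x5 - 3.0 * x6 + C * x5 * x6 + x5 * x6 * x6
                        + beta * (x4 - x6))
    return out


@njit(cache=True)
def jac4(x, H, C, beta, gamma_t):
    """Analytic Jacobian of the four-component vector field (times gamma_t)."""
    x1, x2, x3, x4 = x[0], x[1], x[2], x[3]
    J = np.zeros((4, 4))
    J[0, 0] = 1.0 - C * x2 - x2 * x2
    J[0, 1] = -1.0 - C * x1 - 2.0 * x1 * x2
    J[1, 0] = H + C * x2 + x2 * x2
    J[1, 1] = -3.0 + C * x1 + 2.0 * x1 * x2 - beta
    J[1, 3] = beta
    J[2, 2] = 1.0 - C * x4 - x4 * x4
    J[2, 3] = -1.0 - C * x3 - 2.0 * x3 * x4
    J[3, 1] = 2.0 * beta
    J[3, 2] = H + C * x4 + x4 * x4
    J[3, 3] = -3.0 + C * x3 + 2.0 * x3 * x4 - 2.0 * beta
    return gamma_t * J


@njit(cache=True)
def rk4_traj4(x0, H, C, beta, gamma_t, dt, n_steps):
    """Fixed-step RK4 sweep of the 4-system.

    Returns (states, ok): states has shape (n_steps+1, 4); ok is False when
    the divergence guard tripped (states is truncated garbage past that row).
    """
    out = np.empty((n_steps + 1, 4))
    out[0] = x0
    x = x0.copy()
    for i in range(n_steps):
        k1 = rhs4(x, H, C, beta, gamma_t)
        k2 = rhs4(x + 0.5 * dt * k1, H, C, beta, gamma_t)
        k3 = rhs4(x + 0.5 * dt * k2, H, C, beta, gamma_t)
        k4 = rhs4(x + dt * k3, H, C, beta, gamma_t)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = x
        if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
            return out, False
    return out, True


@njit(cache=True)
def rk4_traj6(x0, H, C, beta, gamma_t, dt, n_steps):
    """Fixed-step RK4 sweep of the 6-system; same contract as rk4_traj4."""
    out = np.empty((n_steps + 1, 6))
    out[0] = x0
    x = x0.copy()
    for i in range(n_steps):
        k1 = rhs6(x, H, C, beta, gamma_t)
        k2 = rhs6(x + 0.5 * dt * k1, H, C, beta, gamma_t)
        k3 = rhs6(x + 0.5 * dt * k2, H, C, beta, gamma_t)
        k4 = rhs6(x + dt * k3, H, C, beta, gamma_t)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = x
        if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
            return out, False
    return out, True


@njit(cache=True)
def rk4_variational(x0, H, C, beta, gamma_t, dt, n_steps):
    """Co-integrate the 4-state and the 4x4 fundamental matrix M' = J(x) M.

    Returns (x_final, M, ok).  Used for monodromy matrices in Floquet
    analysis; M starts from the identity.
    """
    x = x0.copy()
    M = np.eye(4)
    for i in range(n_steps):
        k1 = rhs4(x, H, C, beta, gamma_t)
        K1 = jac4(x, H, C, beta, gamma_t) @ M
        xa = x + 0.5 * dt * k1
        k2 = rhs4(xa, H, C, beta, gamma_t)
        K2 = jac4(xa, H, C, beta, gamma_t) @ (M + 0.5 * dt * K1)
        xb = x + 0.5 * dt * k2
        k3 = rhs4(xb, H, C, beta, gamma_t)
        K3 = jac4(xb, H, C, beta, gamma_t) @ (M + 0.5 * dt * K2)
        xc = x + dt * k3
        k4 = rhs4(xc, H, C, beta, gamma_t)
        K4 = jac4(xc, H, C, beta, gamma_t) @ (M + dt * K3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        M = M + (dt / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
            return x, M, False
    return x, M, True


@njit(cache=True)
def lms_epoch(Z, y, w, b, lr, order):
    """One delta-rule sweep over the samples in the given order.

    Updates the weight vector in place and returns the new intercept.
    """
    for n in range(order.shape[0]):
        i = order[n]
        pred = b
        for j in range(w.shape[0]):
            pred += Z[i, j] * w[j]
        err = pred - y[i]
        for j in range(w.shape[0]):
            w[j] -= lr * err * Z[i, j]
        b -= lr * err
    return b


@njit(cache=True)
def benettin_tangent(x0, v0, H, C, beta, gamma_t, dt, n_transient,
                     n_steps, renorm_every):
    """Benettin largest-Lyapunov sweep.

    Integrates the state through n_transient steps, then co-integrates one
    tangent vector via the variational equation for n_steps, renormalizing
    every `renorm_every` steps and accumulating log stretch factors.

    Returns (log_sum, t_accumulated, ok).
    """
    x = x0.copy()
    for i in range(n_transient):
        k1 = rhs4(x, H, C, beta, gamma_t)
        k2 = rhs4(x + 0.5 * dt * k1, H, C, beta, gamma_t)
        k3 = rhs4(x + 0.5 * dt * k2, H, C, beta, gamma_t)
        k4 = rhs4(x + dt * k3, H, C, beta, gamma_t)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
            return 0.0, 0.0, False
    v = v0.copy()
    log_sum = 0.0
    for i in range(n_steps):
        k1 = rhs4(x, H, C, beta, gamma_t)
        K1 = jac4(x, H, C, beta, gamma_t) @ v
        xa = x + 0.5 * dt * k1
        k2 = rhs4(xa, H, C, beta, gamma_t)
        K2 = jac4(xa, H, C, beta, gamma_t) @ (v + 0.5 * dt * K1)
        xb = x + 0.5 * dt * k2
        k3 = rhs4(xb, H, C, beta, gamma_t)
        K3 = jac4(xb, H, C, beta, gamma_t) @ (v + 0.5 * dt * K2)
        xc = x + dt * k3
        k4 = rhs4(xc, H, C, beta, gamma_t)
        K4 = jac4(xc, H, C, beta, gamma_t) @ (v + dt * K3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        v = v + (dt / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        if np.max(np.abs(x)) > DIVERGENCE_THRESHOLD:
            return log_sum, i * dt, False
        if (i + 1) % renorm_every == 0:
            nv = np.sqrt((v * v).sum())
            log_sum += np.log(nv)
            v = v / nv
    return log_sum, n_steps * dt, True
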