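"""Dynamical-systems analysis of the four-component oscillator model.

Implements the machinery needed to reconstruct the model's route to chaos
(Ruelle-Takens-Newhouse: Hopf -> period doubling -> torus -> strange
attractor) as the control parameter H decreases:

* global Newton census of equilibria and their linear stability,
* continuation of the stationary branch and bisection of the Hopf point,
* periodic orbits by Poincare-section Newton shooting, with Floquet
  multipliers from the monodromy (variational) matrix,
* bisection of the period-doubling (multiplier through -1) and torus
  (complex pair through the unit circle) points,
* Benettin largest Lyapunov exponent and H-scans,
* Poincare sections, attractor classification, and power spectra.

All computations run at ``gamma_t`` as supplied; bifurcation locations are
invariant under the uniform time rescaling (eigenvalues and exponents scale
by ``gamma_t`` without changing sign, multipliers are unchanged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .errors import (BracketError, ContinuationError, DivergedTrajectoryError,
                     DomainError, NoCycleError)
from .model import (DEFAULT_DT, DEFAULT_X0, ModelParams, Trajectory,
                    integrate, jacobian4, rhs4)

logger = logging.getLogger(__name__)

__all__ = [
    "EquilibriumRecord", "CycleSolution", "BifurcationPoint",
    "LyapunovScan", "SpectrumResult", "AttractorClass",
    "find_equilibria", "find_hopf", "stationary_branch_threshold",
    "find_limit_cycle", "locate_attractor_cycle", "monodromy",
    "find_period_doubling", "find_torus_bifurcation",
    "largest_lyapunov", "lyapunov_scan", "poincare_section",
    "classify_attractor", "power_spectrum",
]

#: Step used for variational/Floquet integrations (finer than the default
#: trajectory step because bifurcation points are resolved to ~1e-6 in H).
FLOQUET_DT = 0.001


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class EquilibriumRecord:
    """A stationary state with its Jacobian eigenvalues."""
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class CycleSolution:
    """A located periodic orbit of the four-component system.

    ``anchor`` lies on the Poincare section x[section_index] = section_level;
    ``multipliers`` are the eigenvalues of the one-period monodromy matrix
    (one of them is the trivial flow multiplier ~ 1).
    """
    anchor: np.ndarray
    period: float
    multipliers: np.ndarray
    stable: bool
    residual: float
    section_index: int = 1
    section_level: float = 0.0

    def nontrivial_multipliers(self, tol: float = 1e-3) -> np.ndarray:
        """Multipliers with the trivial (closest-to-1) one removed."""
        i = int(np.argmin(np.abs(self.multipliers - 1.0)))
        if abs(self.multipliers[i] - 1.0) > tol:
            logger.warning("trivial multiplier off unity by %.2e",
                           abs(self.multipliers[i] - 1.0))
        return np.delete(self.multipliers, i)


@dataclass
class BifurcationPoint:
    """A codimension-one bifurcation located by bisection in H."""
    kind: str                 # 'hopf' | 'period_doubling' | 'torus'
    H_star: float
    witness: np.ndarray       # critical eigenvalue/multiplier (pair)
    cycle: CycleSolution | None = None
    equilibrium: np.ndarray | None = None


@dataclass
class LyapunovScan:
    H_values: np.ndarray
    lambda_max: np.ndarray

    def __post_init__(self):
        if len(self.H_values) != len(self.lambda_max):
            raise ValueError("grids must have equal length")


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    power: np.ndarray
    peaks: np.ndarray         # frequencies of dominant local maxima


@dataclass
class AttractorClass:
    """Outcome of :func:`classify_attractor`.

    ``kind`` is one of 'equilibrium', 'periodic', 'quasiperiodic',
    'chaotic'; for periodic attractors ``n`` counts distinct Poincare
    clusters (1 = simple loop, 2 = period-doubled appearance, ...).
    """
    kind: str
    n: int | None = None
    lambda_max: float | None = None

    def __str__(self) -> str:
        return f"periodic({self.n})" if self.kind == "periodic" else self.kind


# --------------------------------------------------------------------------
# equilibria
# --------------------------------------------------------------------------

def _newton_equilibrium(x0: np.ndarray, params: ModelParams,
                        tol: float = 1e-12, max_iter: int = 60
                        ) -> np.ndarray | None:
    """Newton iteration for rhs4 = 0; None on failure."""
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        f = _kernels.rhs4(x, params.H, params.C, params.beta, params.gamma_t)
        if np.max(np.abs(f)) < tol:
            return x
        J = _kernels.jac4(x, params.H, params.C, params.beta, params.gamma_t)
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(dx)) or np.max(np.abs(dx)) > 1e3:
            return None
        x = x + dx
    return None


def _record(state: np.ndarray, params: ModelParams) -> EquilibriumRecord:
    ev = np.linalg.eigvals(jacobian4(state, params))
    return EquilibriumRecord(state=state, eigenvalues=ev,
                             stable=bool(np.max(ev.real) < 0.0))


def find_equilibria(params: ModelParams, search_box: float = 3.0,
                    n_starts: int = 5) -> list[EquilibriumRecord]:
    """Global census of stationary states by Newton from a uniform grid.

    Starts span ``[-search_box, search_box]^4`` with ``n_starts`` points per
    axis.  Converged roots are deduplicated at 1e-6; the origin (always a
    stationary state) is included regardless.
    """
    if n_starts < 1:
        raise DomainError("n_starts must be >= 1")
    grid = np.linspace(-search_box, search_box, n_starts)
    roots: list[np.ndarray] = [np.zeros(4)]
    n_failed = 0
    for a in grid:
        for b in grid:
            for c in grid:
                for d in grid:
                    r = _newton_equilibrium(np.array([a, b, c, d]), params)
                    if r is None or np.max(np.abs(r)) > 10 * search_box:
                        n_failed += 1
                        continue
                    if not any(np.max(np.abs(r - q)) < 1e-6 for q in roots):
                        roots.append(r)
    if n_failed:
        logger.debug("find_equilibria: %d non-convergent starts dropped",
                     n_failed)
    return [_record(r, params) for r in roots]


def _stable_nontrivial(records: Sequence[EquilibriumRecord]
                       ) -> list[EquilibriumRecord]:
    out = [r for r in records
           if r.stable and np.max(np.abs(r.state)) > 1e-6]
    # deterministic order: largest-amplitude branch first
    out.sort(key=lambda r: -float(np.max(np.abs(r.state))))
    return out


def _continue_equilibrium(x: np.ndarray, params: ModelParams
                          ) -> np.ndarray:
    r = _newton_equilibrium(x, params)
    if r is None:
        raise ContinuationError(
            f"equilibrium branch lost at H={params.H}")
    return r


def find_hopf(params_base: ModelParams,
              H_interval: tuple[float, float] = (2.0, 15.0)
              ) -> BifurcationPoint:
    """Hopf point of the stationary branch by continuation + bisection.

    At the upper end of ``H_interval`` the census must contain a stable
    non-trivial equilibrium; that branch is followed down in H (Newton
    warm starts) and the sign change of the leading eigenvalue real part is
    bisected to 1e-6 in H.  The witness is the critical complex pair.
    """
    lo, hi = H_interval
    if not lo < hi:
        raise DomainError("H_interval must satisfy lo < hi")
    stable = _stable_nontrivial(find_equilibria(params_base.with_H(hi)))
    if not stable:
        raise BracketError(
            f"no stable non-trivial equilibrium at H={hi}")
    x = stable[0].state.copy()

    def leading(H: float, guess: np.ndarray) -> tuple[float, np.ndarray]:
        r = _continue_equilibrium(guess, params_base.with_H(H))
        ev = np.linalg.eigvals(jacobian4(r, params_base.with_H(H)))
        return float(np.max(ev.real)), r

    # walk down to bracket the sign change
    step = 0.05
    H_prev, m_prev, x_prev = hi, leading(hi, x)[0], x
    if m_prev >= 0:
        raise BracketError(f"equilibrium at H={hi} is not stable")
    bracket = None
    H_cur = hi
    while H_cur - step >= lo - 1e-12:
        H_cur -= step
        m_cur, x_cur = leading(H_cur, x_prev)
        if m_cur > 0:
            bracket = (H_cur, x_cur, H_prev, x_prev)
            break
        H_prev, m_prev, x_prev = H_cur, m_cur, x_cur
    if bracket is None:
        raise BracketError(
            f"no loss of stability of the stationary branch in {H_interval}")
    a, xa, b, xb = bracket   # m(a) > 0 > m(b), a < b
    while b - a > 1e-6:
        mid = 0.5 * (a + b)
        m, xm = leading(mid, 0.5 * (xa + xb))
        if m > 0:
            a, xa = mid, xm
        else:
            b, xb = mid, xm
    H_star = 0.5 * (a + b)
    pars = params_base.with_H(H_star)
    x_star = _continue_equilibrium(0.5 * (xa + xb), pars)
    ev = np.linalg.eigvals(jacobian4(x_star, pars))
    order = np.argsort(-ev.real)
    witness = ev[order[:2]]
    if abs(witness[0].imag) < 1e-12:
        raise ContinuationError(
            "leading eigenvalue at criticality is real; not a Hopf point")
    logger.info("Hopf located at H=%.7f (witness %s)", H_star, witness)
    return BifurcationPoint(kind="hopf", H_star=H_star, witness=witness,
                            equilibrium=x_star)


def stationary_branch_threshold(params_base: ModelParams,
                                H_range: tuple[int, int] = (1, 20),
                                H_seed: int = 12) -> int | None:
    """Smallest integer H at which the diagram's stationary branch is stable.

    The branch examined is the stationary family of the bifurcation diagram
    — the non-trivial equilibrium branch that undergoes the Hopf bifurcation
    — continued across integer H values from a seed where it is stable.
    (A global census additionally finds a second, disconnected stationary
    family; see :func:`find_equilibria`.)  Returns None when the branch is
    never stable on the range.
    """
    lo, hi = int(H_range[0]), int(H_range[1])
    H_seed = min(max(H_seed, lo), hi)
    stable = _stable_nontrivial(find_equilibria(params_base.with_H(H_seed)))
    if not stable:
        raise BracketError(f"no stable non-trivial equilibrium at H={H_seed}")
    x_seed = stable[0].state.copy()
    status: dict[int, bool] = {}

    def walk(direction: int):
        x = x_seed.copy()
        H = H_seed
        while lo <= H <= hi:
            try:
                r = _continue_equilibrium(x, params_base.with_H(H))
            except ContinuationError:
                break
            ev = np.linalg.eigvals(jacobian4(r, params_base.with_H(H)))
            status[H] = bool(np.max(ev.real) < 0)
            x = r
            # pre-step to the next integer through intermediate points
            nxt = H + direction
            if not lo <= nxt <= hi:
                break
            ok = True
            for frac in (0.25, 0.5, 0.75):
                r2 = _newton_equilibrium(
                    x, params_base.with_H(H + direction * frac))
                if r2 is None:
                    ok = False
                    break
                x = r2
            if not ok:
                break
            H = nxt
    walk(-1)
    walk(+1)
    stable_ints = sorted(h for h, s in status.items() if s)
    return stable_ints[0] if stable_ints else None


# --------------------------------------------------------------------------
# periodic orbits: shooting + Floquet
# --------------------------------------------------------------------------

def _section_crossings(states: np.ndarray, dt: float, level: float,
                       index: int = 1, direction: int = +1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolated crossings of x[index] = level."""
    a = states[:-1, index] - level
    b = states[1:, index] - level
    if direction >= 0:
        w = np.where((a < 0) & (b >= 0))[0]
    else:
        w = np.where((a > 0) & (b <= 0))[0]
    if len(w) == 0:
        return np.empty(0), np.empty((0, states.shape[1]))
    s = a[w] / (a[w] - b[w])
    times = (w + s) * dt
    points = states[w] + s[:, None] * (states[w + 1] - states[w])
    return times, points


def _shoot(params: ModelParams, x_guess: np.ndarray, T_guess: float,
           level: float, dt: float = FLOQUET_DT, tol: float = 1e-11,
           max_iter: int = 40, max_step: float = 0.05
           ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, float] | None:
    """Newton shooting on the section x2 = level.

    Unknowns are (x1, x3, x4, T); x2 is pinned to the section level.  The
    Jacobian of the return condition combines the monodromy matrix with the
    flow direction, so Floquet multipliers come for free at convergence.
    Returns (anchor, period, multipliers, monodromy, residual) or None.
    """
    x = np.asarray(x_guess, dtype=float).copy()
    x[1] = level
    T = float(T_guess)
    for _ in range(max_iter):
        n = max(int(round(T / dt)), 10)
        h = T / n
        xT, M, ok = _kernels.rk4_variational(
            x, params.H, params.C, params.beta, params.gamma_t, h, n)
        if not ok:
            return None
        F = xT - x
        res = float(np.max(np.abs(F)))
        if res < tol:
            mult = np.linalg.eigvals(M)
            return x, T, mult, M, res
        fT = _kernels.rhs4(xT, params.H, params.C, params.beta,
                           params.gamma_t)
        A = np.empty((4, 4))
        MI = M - np.eye(4)
        A[:, 0] = MI[:, 0]
        A[:, 1] = MI[:, 2]
        A[:, 2] = MI[:, 3]
        A[:, 3] = fT
        try:
            d = np.linalg.solve(A, -F)
        except np.linalg.LinAlgError:
            return None
        scale = min(1.0, max_step / max(np.max(np.abs(d[:3])),
                                        abs(d[3]) / max(T, 1e-9)))
        x[0] += scale * d[0]
        x[2] += scale * d[1]
        x[3] += scale * d[2]
        T += scale * d[3]
        if not np.isfinite(T) or T <= 0:
            return None
    return None


def _cycle_from_shoot(result, level: float) -> CycleSolution:
    x, T, mult, M, res = result
    nontriv = np.delete(mult, int(np.argmin(np.abs(mult - 1.0))))
    return CycleSolution(anchor=x, period=T, multipliers=mult,
                         stable=bool(np.max(np.abs(nontriv)) < 1.0),
                         residual=res, section_index=1, section_level=level)


def find_limit_cycle(params: ModelParams, x_guess, T_guess: float,
                     dt: float = FLOQUET_DT, tol: float = 1e-11,
                     max_iter: int = 40) -> CycleSolution:
    """Converge a periodic orbit by Newton shooting from a nearby guess.

    The Poincare section is the hyperplane x2 = x_guess[1] with positive
    crossing direction; ``T_guess`` must be within roughly 50% of the true
    period.
    """
    x_guess = np.asarray(x_guess, dtype=float)
    level = float(x_guess[1])
    result = _shoot(params, x_guess, T_guess, level, dt=dt, tol=tol,
                    max_iter=max_iter)
    if result is None:
        raise NoCycleError(
            f"shooting did not converge at H={params.H} "
            f"(guess period {T_guess})")
    return _cycle_from_shoot(result, level)


def locate_attractor_cycle(params: ModelParams, t_transient: float = 500.0,
                           t_run: float = 300.0, dt: float = DEFAULT_DT,
                           x0=None, return_tol: float = 0.02
                           ) -> CycleSolution:
    """Locate the attracting periodic orbit reached from an initial state.

    Integrates through the transient, takes Poincare crossings of the
    attractor at its mean-x2 plane, estimates the period as the first
    return of the section state to its starting point (within
    ``return_tol`` of the attractor amplitude), then polishes by shooting.
    """
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    tr = integrate(rhs4, x0, dt, int(round(t_transient / dt)), params)
    tr2 = integrate(rhs4, tr.states[-1], dt, int(round(t_run / dt)), params)
    level = float(tr2.states[:, 1].mean())
    times, points = _section_crossings(tr2.states, dt, level)
    if len(times) < 2:
        raise NoCycleError(f"attractor at H={params.H} does not cross the "
                           "section; not a periodic orbit?")
    amp = float(np.ptp(tr2.states, axis=0).max())
    for j in range(1, len(times)):
        if np.max(np.abs(points[j] - points[0])) < return_tol * amp:
            return find_limit_cycle(params, points[0], times[j] - times[0])
    raise NoCycleError(f"no periodic return detected at H={params.H}")


def monodromy(cycle: CycleSolution, params: ModelParams,
              dt: float = FLOQUET_DT, return_matrix: bool = False):
    """Floquet multipliers of a converged cycle, recomputed from scratch.

    Integrates the variational equation u' = J(x(t)) u around the orbit from
    the identity and returns the eigenvalues of the fundamental matrix
    (and the matrix itself with ``return_matrix=True``; its determinant is
    the well-conditioned evaluation of the multiplier product even when one
    multiplier underflows eigensolver precision).
    """
    n = max(int(round(cycle.period / dt)), 10)
    h = cycle.period / n
    _, M, ok = _kernels.rk4_variational(
        cycle.anchor, params.H, params.C, params.beta, params.gamma_t, h, n)
    if not ok:
        raise DivergedTrajectoryError("variational flow diverged")
    mult = np.linalg.eigvals(M)
    return (mult, M) if return_matrix else mult


def monodromy_logdet(cycle: CycleSolution, params: ModelParams,
                     dt: float = FLOQUET_DT, n_segments: int = 16) -> float:
    """log of the Floquet multiplier product, accumulated stably.

    Strongly dissipative cycles contract phase-space volume by many orders
    of magnitude per period, underflowing any single determinant in double
    precision; multiplying segment determinants in log space keeps full
    relative accuracy.  By the Abel-Jacobi-Liouville identity the result
    equals the Jacobian trace integrated once around the orbit.
    """
    n = max(int(round(cycle.period / dt)), 10 * n_segments)
    n_seg, rem = divmod(n, n_segments)
    h = cycle.period / n
    x = cycle.anchor.copy()
    log_det = 0.0
    for s in range(n_segments):
        steps = n_seg + (1 if s < rem else 0)
        x, M, ok = _kernels.rk4_variational(
            x, params.H, params.C, params.beta, params.gamma_t, h, steps)
        if not ok:
            raise DivergedTrajectoryError("variational flow diverged")
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise ContinuationError("segment determinant not positive; "
                                    "flow map should preserve orientation")
        log_det += ld
    return log_det


def _survey_cycles(params: ModelParams, t_transient: float = 3000.0,
                   t_run: float = 1000.0, dt: float = DEFAULT_DT,
                   n_starts: int = 8, k_max: int = 8,
                   x0=None) -> list[CycleSolution]:
    """Multi-start shooting survey of periodic orbits (stable and unstable).

    Section crossings of a long default trajectory supply anchors and
    candidate periods (sums of successive return intervals); every
    combination is polished by Newton shooting and distinct orbits are
    collected.  Long transients pass close to unstable cycles embedded in
    the attractor's neighbourhood, which seeds their discovery.
    """
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    tr = integrate(rhs4, x0, dt, int(round(t_transient / dt)), params)
    tr2 = integrate(rhs4, tr.states[-1], dt, int(round(t_run / dt)), params)
    level = float(tr2.states[:, 1].mean())
    times, points = _section_crossings(tr2.states, dt, level)
    found: list[CycleSolution] = []
    if len(times) < k_max + 2:
        return found
    i_max = min(len(times) - k_max - 1, 5 * n_starts)
    for i0 in range(0, i_max, 5):
        for k in range(1, k_max + 1):
            T_guess = times[i0 + k] - times[i0]
            if T_guess > 30.0:
                continue
            result = _shoot(params, points[i0], T_guess, level,
                            max_iter=25)
            if result is None:
                continue
            x, T, mult, M, res = result
            if T < 0.5:
                continue
            duplicate = False
            for f in found:
                ratio = T / f.period
                if (abs(ratio - round(ratio)) < 1e-6 and round(ratio) >= 1
                        and np.max(np.abs(x - f.anchor)) < 1e-6):
                    duplicate = True
                    break
            if not duplicate:
                found.append(_cycle_from_shoot(result, level))
    return found


def _real_pd_candidate(cycle: CycleSolution) -> float | None:
    """The real multiplier nearest -1, if any (negative, real)."""
    m = cycle.nontrivial_multipliers()
    real = m[np.abs(m.imag) < 1e-9].real
    real = real[real < -0.3]
    if len(real) == 0:
        return None
    return float(real[np.argmin(np.abs(real + 1.0))])


def find_period_doubling(params_base: ModelParams,
                         H_interval: tuple[float, float] = (2.728, 2.746)
                         ) -> BifurcationPoint:
    """Period-doubling point: real Floquet multiplier through -1.

    At the upper end of ``H_interval`` periodic orbits are surveyed by
    multi-start shooting and the orbit whose real multiplier lies nearest
    -1 is selected; that orbit is continued down in H and the crossing of
    the multiplier through -1 is bisected to 1e-6 in H.  The default
    interval brackets the model's period-doubling point adjacent to (just
    above) the torus bifurcation.
    """
    lo, hi = H_interval
    if not lo < hi:
        raise DomainError("H_interval must satisfy lo < hi")
    survey = _survey_cycles(params_base.with_H(hi))
    candidates = [(c, mu) for c in survey
                  if (mu := _real_pd_candidate(c)) is not None
                  and -3.0 < mu < -0.3]
    if not candidates:
        raise ContinuationError(
            f"no cycle with a real multiplier near -1 found at H={hi}")
    cycle, mu = min(candidates, key=lambda cm: abs(cm[1] + 1.0))
    logger.info("PD survey at H=%g: tracking cycle T=%.5f (mu=%.5f)",
                hi, cycle.period, mu)

    def track(H: float, guess: CycleSolution) -> tuple[CycleSolution, float]:
        c = find_limit_cycle(params_base.with_H(H), guess.anchor,
                             guess.period)
        mu = _real_pd_candidate(c)
        if mu is None:
            raise ContinuationError(
                f"critical multiplier became complex at H={H}")
        return c, mu

    # walk down to bracket mu = -1
    H_prev, c_prev, mu_prev = hi, cycle, mu
    bracket = None
    step = 0.002
    H_cur = hi
    while H_cur - step >= lo - 1e-12:
        H_cur -= step
        c_cur, mu_cur = track(H_cur, c_prev)
        if (mu_cur + 1.0) * (mu_prev + 1.0) < 0:
            bracket = (H_cur, c_cur, H_prev, c_prev)
            break
        H_prev, c_prev, mu_prev = H_cur, c_cur, mu_cur
    if bracket is None:
        raise BracketError(
            f"multiplier does not cross -1 inside {H_interval}")
    a, ca, b, cb = bracket
    mu_a = _real_pd_candidate(ca)
    while b - a > 1e-6:
        mid = 0.5 * (a + b)
        cm, mu_m = track(mid, ca if mid - a < b - mid else cb)
        if (mu_m + 1.0) * (mu_a + 1.0) > 0:
            a, ca, mu_a = mid, cm, mu_m
        else:
            b, cb = mid, cm
    H_star = 0.5 * (a + b)
    c_star, mu_star = track(H_star, ca)
    logger.info("period doubling located at H=%.7f (mu=%.6f)",
                H_star, mu_star)
    return BifurcationPoint(kind="period_doubling", H_star=H_star,
                            witness=np.array([mu_star]), cycle=c_star)


def find_torus_bifurcation(params_base: ModelParams,
                           H_interval: tuple[float, float] = (2.72, 2.75),
                           H_locate: float = 2.80) -> BifurcationPoint:
    """Torus (Neimark-Sacker) point: complex pair through the unit circle.

    The attracting cycle is located at ``H_locate`` (where it is the
    default-state attractor), continued down into ``H_interval``, and the
    crossing of the non-real multiplier pair's modulus through 1 is
    bisected to 1e-6 in H.
    """
    lo, hi = H_interval
    if not lo < hi or H_locate < hi:
        raise DomainError("need lo < hi <= H_locate")
    cycle = locate_attractor_cycle(params_base.with_H(H_locate))

    def track(H: float, guess: CycleSolution) -> tuple[CycleSolution, float]:
        c = find_limit_cycle(params_base.with_H(H), guess.anchor,
                             guess.period)
        m = c.nontrivial_multipliers()
        m = m[np.abs(m) > 1e-6]
        return c, float(np.max(np.abs(m)))

    c_prev = cycle
    for H in np.arange(H_locate, hi - 1e-12, -0.005):
        c_prev, _ = track(H, c_prev)
    H_prev, (c_prev, m_prev) = hi, track(hi, c_prev)
    if m_prev >= 1.0:
        raise BracketError(f"cycle already unstable at H={hi}")
    bracket = None
    step = 0.002
    H_cur = hi
    while H_cur - step >= lo - 1e-12:
        H_cur -= step
        c_cur, m_cur = track(H_cur, c_prev)
        if m_cur >= 1.0:
            bracket = (H_cur, c_cur, H_prev, c_prev)
            break
        H_prev, c_prev, m_prev = H_cur, c_cur, m_cur
    if bracket is None:
        raise BracketError(
            f"multiplier modulus does not cross 1 inside {H_interval}")
    a, ca, b, cb = bracket     # m(a) > 1 > m(b), a < b
    while b - a > 1e-6:
        mid = 0.5 * (a + b)
        cm, m_m = track(mid, ca if mid - a < b - mid else cb)
        if m_m > 1.0:
            a, ca = mid, cm
        else:
            b, cb = mid, cm
    H_star = 0.5 * (a + b)
    c_star, _ = track(H_star, ca)
    m = c_star.nontrivial_multipliers()
    pair = m[np.argsort(-np.abs(m))][:2]
    if abs(pair[0].imag) < 1e-6:
        raise ContinuationError(
            "critical multiplier pair is real; not a torus point")
    logger.info("torus bifurcation located at H=%.7f (|mu|=%.6f)",
                H_star, abs(pair[0]))
    return BifurcationPoint(kind="torus", H_star=H_star, witness=pair,
                            cycle=c_star)


# --------------------------------------------------------------------------
# Lyapunov exponents
# --------------------------------------------------------------------------

def largest_lyapunov(params: ModelParams, x0=None,
                     t_transient: float = 500.0, t_total: float = 4500.0,
                     renorm_dt: float = 1.0, dt: float = DEFAULT_DT
                     ) -> float:
    """Largest Lyapunov exponent by the Benettin tangent-vector method.

    One tangent vector (seeded deterministically along x1) is propagated
    with the variational equation and renormalized every ``renorm_dt``;
    the exponent is the time-averaged log stretch after the transient, in
    units of inverse (gamma_t-scaled) time.
    """
    if t_total <= t_transient:
        raise DomainError("t_total must exceed t_transient")
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    n_tr = int(round(t_transient / dt))
    n = int(round((t_total - t_transient) / dt))
    renorm_every = max(int(round(renorm_dt / dt)), 1)
    v0 = np.array([1.0, 0.0, 0.0, 0.0])
    log_sum, t_acc, ok = _kernels.benettin_tangent(
        x0, v0, params.H, params.C, params.beta, params.gamma_t,
        dt, n_tr, n, renorm_every)
    if not ok:
        raise DivergedTrajectoryError(
            f"trajectory diverged during Lyapunov run (H={params.H})")
    return log_sum / t_acc


def lyapunov_scan(params_base: ModelParams,
                  H_range: tuple[float, float], step: float = 0.009,
                  **lyapunov_kwargs) -> LyapunovScan:
    """Largest Lyapunov exponent on a uniform H grid.

    Per-point failures (diverged trajectories) are recorded as NaN rather
    than aborting the scan.
    """
    lo, hi = H_range
    if not lo < hi:
        raise DomainError("H_range must satisfy lo < hi")
    n = int(np.floor((hi - lo) / step)) + 1
    H_values = lo + step * np.arange(n)
    lam = np.empty(n)
    for i, H in enumerate(H_values):
        try:
            lam[i] = largest_lyapunov(params_base.with_H(float(H)),
                                      **lyapunov_kwargs)
        except DivergedTrajectoryError:
            logger.warning("lyapunov_scan: divergence at H=%g", H)
            lam[i] = np.nan
    return LyapunovScan(H_values=H_values, lambda_max=lam)


# --------------------------------------------------------------------------
# sections, classification, spectra
# --------------------------------------------------------------------------

def poincare_section(traj: Trajectory,
                     plane: tuple[int, float, int] = (1, 0.0, +1)
                     ) -> np.ndarray:
    """Intersections of a trajectory with a coordinate hyperplane.

    ``plane`` is (coordinate index, level, crossing direction); points are
    obtained by linear interpolation between bracketing samples and only
    crossings in the requested direction are kept.  Returns an array of
    section points (possibly empty).
    """
    index, level, direction = plane
    _, points = _section_crossings(traj.states, traj.dt, level,
                                   index=index, direction=direction)
    return points


def _cluster_count(points: np.ndarray, tol: float = 1e-3,
                   max_clusters: int = 64) -> int:
    """Greedy clustering of section points at Chebyshev tolerance tol."""
    reps: list[np.ndarray] = []
    for p in points:
        for r in reps:
            if np.max(np.abs(p - r)) < tol:
                break
        else:
            reps.append(p)
            if len(reps) > max_clusters:
                return len(reps)
    return len(reps)


def classify_attractor(params: ModelParams, x0=None,
                       dt: float = DEFAULT_DT, t_transient: float = 500.0,
                       t_run: float = 300.0, cluster_tol: float = 1e-3,
                       chaos_threshold: float = 0.01,
                       max_periodic_clusters: int = 8) -> AttractorClass:
    """Classify the attractor reached from an initial state.

    The decision sequence, after discarding the transient: a state that has
    stopped moving is an equilibrium; a largest Lyapunov exponent above the
    chaos threshold means chaotic; at most ``max_periodic_clusters``
    distinct Poincare clusters means periodic(n); otherwise a vanishing
    exponent with a dense section means quasiperiodic.

    The default initial state is the standard small perturbation of the
    origin; pass ``x0`` explicitly to resolve a particular attractor in
    multistable regimes (several attractors coexist near the torus
    bifurcation).
    """
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    tr = integrate(rhs4, x0, dt, int(round(t_transient / dt)), params)
    tr2 = integrate(rhs4, tr.states[-1], dt, int(round(t_run / dt)), params)
    if float(np.ptp(tr2.states, axis=0).max()) < 1e-6:
        return AttractorClass(kind="equilibrium")
    lam = largest_lyapunov(params, x0=x0, dt=dt)
    if lam > chaos_threshold:
        return AttractorClass(kind="chaotic", lambda_max=lam)
    level = float(tr2.states[:, 1].mean())
    points = poincare_section(
        Trajectory(times=tr2.times, states=tr2.states, params=params,
                   dt=dt),
        plane=(1, level, +1))
    n_clusters = _cluster_count(points, tol=cluster_tol,
                                max_clusters=max_periodic_clusters + 1)
    if 1 <= n_clusters <= max_periodic_clusters:
        return AttractorClass(kind="periodic", n=n_clusters, lambda_max=lam)
    if abs(lam) <= chaos_threshold:
        return AttractorClass(kind="quasiperiodic", lambda_max=lam)
    return AttractorClass(kind="equilibrium", lambda_max=lam)


def power_spectrum(values, sample_rate: float,
                   peak_rel_threshold: float = 1e-3) -> SpectrumResult:
    """One-sided power spectrum of a uniformly sampled series.

    The mean is removed, a Hann window applied, and the series zero-padded
    to the next power of two.  ``power`` is scaled so that its sum equals
    the energy of the windowed, mean-removed signal (Parseval).  Peaks are
    local maxima above ``peak_rel_threshold`` times the maximum power.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DomainError("need a 1-D series with at least 2 samples")
    if sample_rate <= 0:
        raise DomainError("sample_rate must be positive")
    x = x - x.mean()
    w = np.hanning(len(x))
    xw = x * w
    nfft = 1 << int(np.ceil(np.log2(len(x))))
    F = np.fft.rfft(xw, n=nfft)
    power = np.abs(F) ** 2 / nfft
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    thresh = peak_rel_threshold * power.max() if power.max() > 0 else np.inf
    interior = np.arange(1, len(power) - 1)
    is_peak = ((power[interior] > power[interior - 1])
               & (power[interior] >= power[interior + 1])
               & (power[interior] > thresh))
    peak_idx = interior[is_peak]
    order = np.argsort(-power[peak_idx])
    return SpectrumResult(frequencies=freqs, power=power,
                          peaks=freqs[peak_idx[order]])
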