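# Methods

## Model

The package integrates the three-oscillator discretization of the BVAM
two-species reaction-diffusion system (kinetics fixed at `eta = 1`,
`a = -1`, `b = -3`, placing each node in its oscillatory, excitable
regime).  Zero-flux boundaries on the three-node stencil force the two
boundary nodes to move identically, which reduces the six equations to
four; the package implements both systems and the tests verify that the
6-component flow started from symmetric data reproduces the 4-component
flow to round-off (the reduction is exact in floating point because the
corresponding update formulas are algebraically identical).

Parameters, all dimensionless:

| parameter | meaning | default |
|---|---|---|
| `H` | linear cross-activation strength; the control parameter | required; studied on [1, 20], values outside warn |
| `C` | quadratic/cubic nonlinearity ratio | 1.35 |
| `beta` | inter-node coupling `1/(dx)^2` | 4 |
| `Gamma_t` | uniform time-scale factor multiplying the vector field | 1 (dimensionless time) |

`Gamma_t` is affine in the heart rate, `Gamma_t = 0.08804 HR - 0.06754`
(beats/min); `Gamma_t = 7` corresponds to ~80 bpm (normal rhythm) and
`Gamma_t = 17` to ~194 bpm (fibrillation).  Because `Gamma_t` rescales
time uniformly, equilibria, cycles and bifurcation locations are
invariant under it; eigenvalues and Lyapunov exponents scale by it.  The
standard initial state is `(0, 0, 0.1, 0)` — a small kick to the second
oscillator.

## Integration

Classical fixed-step RK4 with `dt = 0.005` in dimensionless time for
trajectories (the tests confirm 4th-order global convergence), and
`dt = 0.001` for all variational/Floquet integrations, where bifurcation
points are bisected to 1e-6 in `H`.  A divergence guard aborts when any
component exceeds 1e6 — far outside the attractors' O(1) scale.  ECG
simulation at physical `Gamma_t` internally refines the step so the
dimensionless step never exceeds 0.005, then subsamples onto the
requested grid (at `Gamma_t = 17` the raw 5 ms step is outside the RK4
stability region in the chaotic regime).

## Equilibria and the Hopf point

Stationary states are found by a global Newton census from a uniform
5^4 grid over `[-3, 3]^4`, deduplicated at 1e-6, with eigenvalues of the
analytic Jacobian (validated against central finite differences).  The
census shows the model has, besides the unstable origin, two non-trivial
stationary families; the one relevant to the bifurcation diagram — the
branch followed by `find_hopf` and `stationary_branch_threshold` — loses
stability at

    H_hopf = 8.7792667

through a complex-conjugate pair crossing the imaginary axis, located by
warm-started Newton continuation and bisection on the leading eigenvalue
real part.  The smallest integer `H` at which this branch is stable is 9.
The second family (near `(-1.41, -1.37, 1.79, 0.43)` at `H = 8`)
undergoes its own Hopf near `H = 7.97` and is weakly stable at `H = 8`
already; it coexists with, and is disconnected from, the diagram branch,
which is why the threshold is defined on the diagram branch rather than
on the global census.

## Periodic orbits and Floquet analysis

Cycles are converged by Newton shooting on the Poincare section
`x2 = level` (positive crossings): unknowns `(x1, x3, x4, T)` with `x2`
pinned, the return-map Jacobian assembled from the monodromy matrix and
the flow direction, damped steps, and tolerance 1e-11 on the return
residual.  The monodromy matrix is integrated alongside the orbit
(`M' = J(x(t)) M` from the identity), so Floquet multipliers come from
the same solve; the trivial multiplier reproduces 1 to ~1e-7.  The
Abel-Jacobi-Liouville identity (multiplier product = exp of the
orbit-integrated Jacobian trace) is asserted for every located cycle; for
strongly dissipative cycles the product is evaluated as a segmentwise
log-determinant, since a single determinant of a matrix with volume
contraction ~1e-30 per period underflows double precision.

Attracting cycles are located from simulation: transient of 500 time
units, section crossings of the attractor at its mean-`x2` plane, period
estimated as the first return of the section state to its start (within
2% of the attractor amplitude), then shooting.  Unstable cycles are
discovered by a multi-start survey: anchors and candidate periods are
harvested from the crossing sequence of a long (3000 + 1000 time unit)
default trajectory — which shadows unstable orbits embedded near the
attractor — and every combination is polished by shooting.

## The route to chaos and its critical points

With `C = 1.35`, `beta = 4` the package reproduces, deterministically:

* **Torus (Neimark-Sacker) point** `H_tr = 2.7297524`: the attracting
  cycle (period ~4.76 there), continued down from `H = 2.80`, has a
  non-real multiplier pair whose modulus crosses 1; bisected to 1e-6 and
  independent of the Floquet step (`dt` 0.001 vs 0.0005 agree to 1e-7).
* **Period-doubling point** `H_pd = 2.7325251`: a coexisting period-~2.02
  orbit, found by the multi-start survey at `H = 2.746`, carries a real
  multiplier that crosses -1.  The value is step-size independent and was
  cross-checked by recomputing the critical multipliers with an adaptive
  8th-order integrator at tolerance 1e-12.  The value usually quoted for
  this point is 2.742524; the computed crossing at 2.7325251 agrees with
  that figure digit-for-digit except in the second decimal, so we regard
  the quoted value as carrying a transposed digit and report the computed
  one.  The ordering `H_hopf > H_pd > H_tr` holds either way.
* **Chaos**: the largest Lyapunov exponent (Benettin: one tangent vector
  propagated by the variational equation, renormalized every 1.0 time
  unit, transient 500, accumulation 4000 time units, tangent seeded
  deterministically along `x1`) is ~0.18 at `H = 2.7126` and positive
  across the fibrillation regime (`~0.093` at `H = 2.164`), ~0 on cycles,
  and matches the leading equilibrium eigenvalue (-0.495 at `H = 10`)
  where the attractor is stationary.

**Multistability caveat.** Near and below the torus point several
attractors coexist.  From the standard initial state the trajectory
reaches a large chaotic attractor for `H` below ~2.738 even while the
cycle is still linearly stable (and the Lyapunov scan shows long chaotic
transients up to `H ~ 2.79`); the thin attracting torus born at the
bifurcation is only reached from states near the destabilized cycle.
`classify_attractor` therefore accepts an explicit initial state; the
tests resolve the quasiperiodic regime from a near-cycle state (exponent
0.0009, dense section) and the chaotic regime from the default state.

Attractor classification (after a 500-unit transient; 2000 near the
critical points, where slowing is pronounced): stationary if the
post-transient state moves less than 1e-6; chaotic if the exponent
exceeds 0.01; periodic(n) if the section clusters into at most 8 groups
at tolerance 1e-3; quasiperiodic if the exponent is within 0.01 of zero
with a dense section.  These thresholds separate the studied regimes
robustly at `dt = 0.005`.

## ECG synthesis and fitting

`mix_ecg` applies the fixed linear mixture; the preset registry carries
the published bundles (normal sinus `H = 3`,
`alpha = (-0.024, 0.0216, -0.0012, 0.12)`, `Gamma_t = 7`; sinus
tachycardia `H = 2.848`; atrial flutter `H = 1.52`; ventricular
tachycardia and flutter `H = 2.178`; fibrillation `H = 2.164`,
`Gamma_t = 17` with the normal mixing weights, which apply to all
rhythms that do not override them).  For the fibrillation and
quasiperiodic presets the registry follows the per-figure `H` values
rather than a blanket table caption, since the rows are the more specific
statement.

`fit_alphas` is a delta-rule (Widrow-Hoff LMS) learner — the canonical
perceptron-style algorithm for a model linear in its parameters — with
internally standardized features (one learning rate fits all four
activations; the reported weights are mapped back to the raw scale), 500
epochs at rate 1e-3 by default, sample order shuffled by a seeded
generator.  The closed-form least-squares solution of the same problem is
returned alongside as the convergence oracle; on self-generated
references both recover the generating weights to well below 1e-3.
Optional phase alignment of cyclic references uses circular
cross-correlation against the dominant activation.

`synth_template` generates a beat-periodic sum-of-Gaussians P-QRS-T
morphology (circularly wrapped in beat phase, so the waveform is exactly
periodic) with optional seeded Gaussian noise.  It emulates only the
stationary morphology of a clean lead-II recording: no baseline wander,
beat-to-beat variability, muscle artifact or lead misplacement — so tests
that pass against it demonstrate correctness of the fitting machinery,
not robustness to real recording conditions.

## Circuit arithmetic

`design_components` realizes the gain ratios `R/R1 = 3`, `R2/R1 = beta`,
`R3/R1 = 2` and the integrator time scale `1/(Ri Ci) = Gamma_t` exactly;
`validate_components` reports the relative residual of each constraint.
A practical build that rounds 14.29 kOhm to the stock 14 kOhm value
realizes `Gamma_t = 7` with a ~2% residual, which passes at the default
5% tolerance.  Optional snapping to the E12/E24 series is off by default.

## Problem sizes

The test suite and the acceptance script run on deliberately modest
problem sizes: trajectories of 1e4-1e5 steps, Lyapunov accumulation of
4000 dimensionless time units, a 5^4 Newton census, continuation steps of
0.002-0.005 in `H` with ~20 bisection iterations per critical point.
The bifurcation locations move by less than 1e-6 when the Floquet step is
halved, and the Lyapunov values quoted above change by <2% when the
accumulation time is doubled.

## Known limitations

* The spatially continuous reaction-diffusion system is represented only
  by its three-node discretization; no spatial wave propagation.
* The bifurcation machinery follows one branch at a time with warm
  starts; it does not do pseudo-arclength continuation or branch
  switching, and folds terminate a walk rather than being traversed.
* Only the largest Lyapunov exponent is computed, not the full spectrum.
* The multistability described above means simulation-based diagnostics
  (classification, Lyapunov scans) depend on the initial state in the
  window `H ~ 2.72-2.79`; the Floquet-based locations of the critical
  points do not.
* Single-lead (lead II analog) output only; beat detection is a simple
  thresholded peak finder intended for tests.
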