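"""Synthetic ECG signals from trajectories of the oscillator model.

A surface electrocardiogram is approximated as a fixed linear mixture of
the four oscillator activations,

    ECG(t) = a1*x1 + a2*x2 + a3*x3 + a4*x4,

the weights expressing how strongly each pacemaker compartment projects
onto the (lead II) body-surface potential.  The module ships the published
parameter bundles for the normal sinus rhythm and the classic arrhythmias,
fits mixing weights to a reference waveform with a delta-rule (LMS)
learner backed by an exact least-squares solution, and generates
sum-of-Gaussians P-QRS-T reference templates that stand in for clinical
recordings when exercising the fitting routine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _kernels
from .errors import (DomainError, GridMismatchError, PresetLookupError,
                     StepSizeError)
from .model import (DEFAULT_DT, DEFAULT_X0, ModelParams, Trajectory,
                    integrate, rhs4)

__all__ = [
    "MixingCoefficients", "RhythmPreset", "ECGSignal", "TemplateSpec",
    "WaveSpec", "mix_ecg", "get_preset", "preset_names", "fit_alphas",
    "synth_template", "simulate_rhythm", "detect_r_peaks",
]


@dataclass(frozen=True)
class MixingCoefficients:
    """Dimensionless weights of the four activations in the ECG mixture."""
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise DomainError("mixing coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.alpha4])

    def __add__(self, other: "MixingCoefficients") -> "MixingCoefficients":
        return MixingCoefficients(*(self.as_array() + other.as_array()))


@dataclass(frozen=True)
class RhythmPreset:
    """Named parameter bundle producing a physiological or pathological ECG."""
    name: str
    H: float
    alphas: MixingCoefficients
    gamma_t: float
    C: float = 1.35
    beta: float = 4.0

    def model_params(self) -> ModelParams:
        return ModelParams(H=self.H, C=self.C, beta=self.beta,
                           gamma_t=self.gamma_t)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RhythmPreset":
        d = dict(d)
        d["alphas"] = MixingCoefficients(**d["alphas"])
        return cls(**d)


@dataclass
class ECGSignal:
    """A scalar ECG time series (times in seconds, uniform sampling)."""
    times: np.ndarray
    values: np.ndarray
    preset: RhythmPreset | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if steps.min() <= 0 or not np.allclose(steps, steps[0],
                                                   rtol=1e-6, atol=1e-12):
                raise ValueError("ECG signal must be uniformly sampled")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


# --------------------------------------------------------------------------
# the published rhythm presets
# --------------------------------------------------------------------------

_NORMAL_ALPHAS = MixingCoefficients(-0.024, 0.0216, -0.0012, 0.12)

_PRESETS: dict[str, RhythmPreset] = {p.name: p for p in [
    # Normal sinus rhythm: H = 3 with the perceptron-fitted lead-II weights
    # and gamma_t = 7 (about 80 bpm).
    RhythmPreset("normal_sinus", H=3.0, alphas=_NORMAL_ALPHAS, gamma_t=7.0),
    RhythmPreset("sinus_tachycardia", H=2.848,
                 alphas=MixingCoefficients(0.0, -0.1, 0.0, 0.0),
                 gamma_t=21.0),
    RhythmPreset("atrial_flutter", H=1.52,
                 alphas=MixingCoefficients(-0.068, 0.028, -0.024, 0.12),
                 gamma_t=13.0),
    RhythmPreset("ventricular_tachycardia", H=2.178,
                 alphas=MixingCoefficients(0.0, 0.0, 0.0, -0.1),
                 gamma_t=21.0),
    RhythmPreset("ventricular_flutter", H=2.178,
                 alphas=MixingCoefficients(0.1, -0.02, -0.01, 0.0),
                 gamma_t=13.0),
    # Ventricular fibrillation: the chaotic regime, sped up to gamma_t = 17;
    # mixing weights as for the normal rhythm.
    RhythmPreset("ventricular_fibrillation", H=2.164,
                 alphas=_NORMAL_ALPHAS, gamma_t=17.0),
    # Quasi-periodic rhythm just below the torus bifurcation.
    RhythmPreset("quasiperiodic", H=2.729, alphas=_NORMAL_ALPHAS,
                 gamma_t=7.0),
]}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str) -> RhythmPreset:
    """Look up a rhythm preset by name; unknown names list the registry."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise PresetLookupError(
            f"unknown rhythm preset {name!r}; valid names: "
            f"{', '.join(preset_names())}") from None


def presets_to_json() -> str:
    return json.dumps({n: p.to_dict() for n, p in _PRESETS.items()},
                      indent=2, sort_keys=True)


def presets_from_json(text: str) -> dict[str, RhythmPreset]:
    return {n: RhythmPreset.from_dict(d)
            for n, d in json.loads(text).items()}


# --------------------------------------------------------------------------
# mixing and simulation
# --------------------------------------------------------------------------

def mix_ecg(traj: Trajectory, alphas: MixingCoefficients,
            preset: RhythmPreset | None = None) -> ECGSignal:
    """Linear mixture of the four activations of a 4-component trajectory."""
    if traj.n_components != 4:
        raise DomainError(
            "mix_ecg needs a 4-component trajectory; integrate the reduced "
            "system (or reduce the 6-component one) first")
    values = traj.states @ alphas.as_array()
    return ECGSignal(times=traj.times.copy(), values=values, preset=preset)


def simulate_rhythm(preset: RhythmPreset | str, duration: float,
                    discard: float = 10.0, dt: float = DEFAULT_DT,
                    return_trajectory: bool = False):
    """Simulate a rhythm preset and return its ECG.

    The preset's gamma_t-scaled system is integrated from the default
    initial state with fixed step ``dt`` (seconds); the first ``discard``
    seconds of transient are dropped before mixing.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if duration <= 0:
        raise DomainError("duration must be positive")
    if discard < 0:
        raise DomainError("discard must be non-negative")
    params = preset.model_params()
    # integrate at a dimensionless step of at most 0.005 (the gamma_t-scaled
    # flow is too fast for RK4 at the raw sampling step when gamma_t is
    # large), then keep every k-th sample to land on the requested grid
    refine = max(1, int(np.ceil(params.gamma_t * dt / 0.005)))
    h = dt / refine
    n_discard = int(round(discard / dt))
    n_keep = int(round(duration / dt))
    traj = integrate(rhs4, DEFAULT_X0, h,
                     (n_discard + n_keep) * refine, params)
    states = traj.states[::refine]
    kept = Trajectory(times=dt * np.arange(n_keep + 1),
                      states=states[n_discard:],
                      params=params, dt=dt,
                      x0=states[n_discard])
    signal = mix_ecg(kept, preset.alphas, preset=preset)
    return (signal, kept) if return_trajectory else signal


def detect_r_peaks(signal: ECGSignal, threshold_frac: float = 0.6,
                   min_separation_s: float = 0.2) -> np.ndarray:
    """Times of R peaks by simple thresholded local-maximum detection.

    Local maxima above ``median + threshold_frac * (max - median)`` are
    kept, enforcing a refractory separation; the fraction is high enough to
    reject P/T deflections.  Intended for test-level beat counting, not for
    clinical-grade beat detection.
    """
    v = signal.values
    t = signal.times
    med = float(np.median(v))
    thr = med + threshold_frac * (float(v.max()) - med)
    idx = np.where((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
                   & (v[1:-1] > thr))[0] + 1
    peaks = []
    last_t = -np.inf
    for i in idx:
        if t[i] - last_t >= min_separation_s:
            peaks.append(t[i])
            last_t = t[i]
        elif peaks and v[i] > v[np.searchsorted(t, peaks[-1])]:
            peaks[-1] = t[i]
            last_t = t[i]
    return np.asarray(peaks)


# --------------------------------------------------------------------------
# fitting the mixing weights
# --------------------------------------------------------------------------

def _align_reference(reference: ECGSignal, traj: Trajectory) -> np.ndarray:
    """Validate grids and return the reference values on the trajectory grid.

    The grids must share the step and length; a circular cross-correlation
    phase alignment absorbs an arbitrary phase offset between reference
    beats and simulated beats.
    """
    if len(reference.times) != len(traj.times):
        raise GridMismatchError(
            f"reference has {len(reference.times)} samples but trajectory "
            f"has {len(traj.times)}; resample first")
    dt_ref = reference.times[1] - reference.times[0]
    if not np.isclose(dt_ref, traj.dt, rtol=1e-6):
        raise GridMismatchError(
            f"reference step {dt_ref} differs from trajectory step {traj.dt}")
    ref = reference.values - reference.values.mean()
    proxy = traj.states[:, 3] - traj.states[:, 3].mean()
    corr = np.fft.irfft(np.fft.rfft(ref) * np.conj(np.fft.rfft(proxy)),
                        n=len(ref))
    shift = int(np.argmax(corr))
    return np.roll(reference.values, -shift)


def fit_alphas(reference: ECGSignal, traj: Trajectory,
               learning_rate: float = 1e-3, epochs: int = 500,
               seed: int = 0, align: bool = False
               ) -> tuple[MixingCoefficients, dict]:
    """Fit mixing weights to a reference waveform.

    A delta-rule (Widrow-Hoff LMS) learner minimizes the mean squared error
    between the mixed trajectory and the reference, sweeping samples in a
    seeded random order; features are standardized internally so one
    learning rate serves all four activations.  The exact least-squares
    solution of the same problem is returned alongside as ``info['alphas_lstsq']``
    and serves as the convergence oracle; ``info['mse']`` is the final
    mean squared error of the LMS weights.

    Set ``align=True`` to phase-align a cyclic reference to the trajectory
    by circular cross-correlation before fitting.
    """
    if traj.n_components != 4:
        raise DomainError("fit_alphas needs a 4-component trajectory")
    y = (_align_reference(reference, traj) if align
         else np.asarray(reference.values, dtype=float))
    if len(y) != len(traj.times):
        raise GridMismatchError("reference/trajectory length mismatch")
    X = traj.states

    a_exact, *_ = np.linalg.lstsq(X, y, rcond=None)

    # standardized features for the iterative learner
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    rng = np.random.default_rng(seed)
    w = np.zeros(4)
    b = 0.0
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        b = _kernels.lms_epoch(Z, y, w, b, learning_rate, order)
        if not (np.all(np.isfinite(w)) and np.isfinite(b)):
            raise StepSizeError(
                f"LMS diverged; reduce learning_rate={learning_rate}")
    alphas_lms = w / sd
    # the intercept absorbs mu @ alphas; report it for diagnostics
    mse = float(np.mean((X @ alphas_lms + (b - mu @ alphas_lms) - y) ** 2))
    info = {
        "alphas_lstsq": MixingCoefficients(*a_exact),
        "intercept": float(b - mu @ alphas_lms),
        "mse": mse,
    }
    return MixingCoefficients(*alphas_lms), info


# --------------------------------------------------------------------------
# synthetic reference templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveSpec:
    """One deflection of the P-QRS-T complex, as a Gaussian bump in phase."""
    center: float    # beat phase, radians in (-pi, pi]
    width: float     # radians, > 0
    amplitude: float # dimensionless

    def __post_init__(self):
        if self.width <= 0:
            raise DomainError("wave width must be positive")


#: Canonical lead-II-like morphology (phases/widths in radians).
DEFAULT_WAVES: dict[str, WaveSpec] = {
    "P": WaveSpec(center=-1.22, width=0.25, amplitude=0.12),
    "Q": WaveSpec(center=-0.26, width=0.10, amplitude=-0.10),
    "R": WaveSpec(center=0.00, width=0.10, amplitude=1.00),
    "S": WaveSpec(center=0.26, width=0.10, amplitude=-0.17),
    "T": WaveSpec(center=1.48, width=0.40, amplitude=0.25),
}


@dataclass(frozen=True)
class TemplateSpec:
    """Specification of a synthetic periodic P-QRS-T reference waveform."""
    heart_rate: float = 60.0           # beats per minute
    waves: tuple = tuple(DEFAULT_WAVES.items())
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise DomainError("heart_rate must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def synth_template(spec: TemplateSpec, duration: float,
                   sample_rate: float) -> ECGSignal:
    """Periodic sum-of-Gaussians P-QRS-T waveform plus optional noise.

    This synthetic template emulates a clean clinical lead-II recording for
    exercising :func:`fit_alphas`; it is a stand-in, not patient data.
    """
    if duration <= 0 or sample_rate <= 0:
        raise DomainError("duration and sample_rate must be positive")
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    beat_period = 60.0 / spec.heart_rate
    # R wave (phase 0) sits mid-beat so edge samples never clip a peak
    phase = 2.0 * np.pi * ((t / beat_period) % 1.0) - np.pi
    v = np.zeros_like(t)
    for _, wave in spec.waves:
        # circular distance keeps the waveform continuous and exactly
        # beat-periodic across the phase wrap
        d = np.mod(phase - wave.center + np.pi, 2.0 * np.pi) - np.pi
        v += wave.amplitude * np.exp(-0.5 * (d / wave.width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return ECGSignal(times=t, values=v)
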