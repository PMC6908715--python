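"""Analog-computer realization: component values for the oscillator circuit.

The model maps onto inverting OPAMP integrator/adder stages with analog
multipliers; the resistor ratios fix the integer gains of the linear terms
and the integrator RC product fixes the time scale:

    R / R1 = 3,   R2 / R1 = beta,   R3 / R1 = 2,   1 / (Ri * Ci) = gamma_t.

Only this component-value arithmetic is modeled; OPAMP nonidealities and
the physical build are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["ComponentSet", "ValidationReport", "design_components",
           "validate_components", "E12_SERIES", "E24_SERIES", "snap_to_series"]

E12_SERIES = (1.0, 1.2, 1.5, 1.8, 2.2, 2.7, 3.3, 3.9, 4.7, 5.6, 6.8, 8.2)
E24_SERIES = (1.0, 1.1, 1.2, 1.3, 1.5, 1.6, 1.8, 2.0, 2.2, 2.4, 2.7, 3.0,
              3.3, 3.6, 3.9, 4.3, 4.7, 5.1, 5.6, 6.2, 6.8, 7.5, 8.2, 9.1)


@dataclass(frozen=True)
class ComponentSet:
    """Resistances (ohms) and the integrator capacitance (farads)."""
    R: float
    R1: float
    R2: float
    R3: float
    Ri: float
    Ci: float

    def __post_init__(self):
        for name in ("R", "R1", "R2", "R3", "Ri", "Ci"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass
class ValidationReport:
    """Relative residuals of the four design constraints."""
    residuals: dict[str, float]
    tolerance: float
    passed: bool

    def __str__(self) -> str:
        lines = [f"constraint residuals (tolerance {self.tolerance:.3g}):"]
        for k, v in self.residuals.items():
            lines.append(f"  {k}: {v:.4g}")
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def snap_to_series(value: float, series=E12_SERIES) -> float:
    """Round a component value to the nearest standard-series value."""
    if value <= 0:
        raise DomainError("value must be positive")
    decade = 10.0 ** np.floor(np.log10(value))
    candidates = np.array(series + (series[0] * 10,)) * decade
    return float(candidates[np.argmin(np.abs(np.log(candidates / value)))])


def design_components(beta: float, gamma_t: float, R1: float,
                      Ci: float, snap_series=None) -> ComponentSet:
    """Component values satisfying the circuit design constraints exactly.

    ``R1`` (ohms) and ``Ci`` (farads) are free choices; the rest follow.
    Pass ``snap_series`` (e.g. ``E12_SERIES``) to round the derived values
    to a standard component series.
    """
    if beta <= 0 or gamma_t <= 0:
        raise DomainError("beta and gamma_t must be positive")
    if R1 <= 0 or Ci <= 0:
        raise DomainError("R1 and Ci must be positive")
    values = {
        "R": 3.0 * R1, "R1": R1, "R2": beta * R1, "R3": 2.0 * R1,
        "Ri": 1.0 / (gamma_t * Ci), "Ci": Ci,
    }
    if snap_series is not None:
        values = {k: snap_to_series(v, snap_series) for k, v in values.items()}
    return ComponentSet(**values)


def validate_components(components: ComponentSet, beta: float,
                        gamma_t: float, tolerance: float = 0.05
                        ) -> ValidationReport:
    """Check a component set against the four ratio/time-scale constraints.

    Each constraint's relative residual is reported; the set passes when
    all residuals are at or below ``tolerance``.  (Practical builds round
    to stock values — e.g. a 14 kOhm / 10 uF integrator realizes
    gamma_t = 7 with a ~2% residual.)
    """
    if tolerance < 0:
        raise DomainError("tolerance must be non-negative")
    c = components
    residuals = {
        "R/R1 = 3": abs(c.R / c.R1 - 3.0) / 3.0,
        f"R2/R1 = beta = {beta:g}": abs(c.R2 / c.R1 - beta) / beta,
        "R3/R1 = 2": abs(c.R3 / c.R1 - 2.0) / 2.0,
        f"1/(Ri*Ci) = gamma_t = {gamma_t:g}":
            abs(1.0 / (c.Ri * c.Ci) - gamma_t) / gamma_t,
    }
    passed = all(v <= tolerance for v in residuals.values())
    return ValidationReport(residuals=residuals, tolerance=tolerance,
                            passed=passed)
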