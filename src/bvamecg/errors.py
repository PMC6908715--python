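"""Exception hierarchy for the bvamecg package."""


class BvamEcgError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(BvamEcgError, ValueError):
    """A state vector contains non-finite components."""


class DivergedTrajectoryError(BvamEcgError, RuntimeError):
    """A trajectory left the divergence guard (|x_i| > threshold)."""


class DomainError(BvamEcgError, ValueError):
    """A parameter value lies outside the mathematically valid domain."""


class BracketError(BvamEcgError, RuntimeError):
    """A bisection interval does not bracket the sought sign change."""


class ContinuationError(BvamEcgError, RuntimeError):
    """A solution branch could not be followed across the requested range."""


class NoCycleError(BvamEcgError, RuntimeError):
    """Newton shooting failed to converge to a periodic orbit."""


class PresetLookupError(BvamEcgError, KeyError):
    """Unknown rhythm preset name."""


class GridMismatchError(BvamEcgError, ValueError):
    """Reference and trajectory are not sampled on the same time grid."""


class StepSizeError(BvamEcgError, RuntimeError):
    """Iterative fitting diverged because the learning rate is too large."""


class ParseError(BvamEcgError, ValueError):
    """A serialized file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
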