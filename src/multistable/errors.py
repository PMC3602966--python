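"""Exception hierarchy for the multistable package."""


class MultistableError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MultistableError, ValueError):
    """A model or protocol parameter violates its constraints."""


class NumericalFailureError(MultistableError, FloatingPointError):
    """The integrator produced a non-finite state."""


class InsufficientDataError(MultistableError, ValueError):
    """Too few dominance periods (or pairs) for the requested statistic."""


class DegenerateFitError(MultistableError, ValueError):
    """Distribution fitting is impossible (e.g. zero-variance sample)."""


class UnclassifiableRegimeError(MultistableError, RuntimeError):
    """The noiseless trajectory met none of the regime criteria."""

    def __init__(self, message, tail=None):
        super().__init__(message)
        self.tail = tail


class SequenceValidationError(MultistableError, ValueError):
    """A reversal sequence violates its structural invariants."""


class SequenceParseError(MultistableError, ValueError):
    """A sequence file could not be parsed."""


class EmptyVolumeError(MultistableError, ValueError):
    """A matching volume contains no points."""


class ConfigurationError(MultistableError, ValueError):
    """An inconsistent scan or grid configuration."""
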