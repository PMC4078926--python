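"""Exception types shared across the package."""


class AudlexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AudlexError):
    """Invalid configuration: bad correlation matrix, negative SD, bad probabilities."""


class SchemaError(AudlexError):
    """A subject table is missing required columns or groups."""


class DegenerateMeasureError(AudlexError):
    """A measure has zero control spread at some standardization step."""

    def __init__(self, measure: str, step: int):
        self.measure = measure
        self.step = step
        super().__init__(
            f"measure {measure!r}: zero control SD at standardization step {step}"
        )


class FitConvergenceError(AudlexError):
    """A psychometric fit failed to converge; carries a diagnostic message."""
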