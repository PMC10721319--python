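"""Exception and warning types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or configuration parameter violates its stated constraints."""


class OutOfRangeError(ValueError):
    """An interval or epoch falls outside the extent of the trace it refers to."""


class InsufficientBaselineError(ValueError):
    """The requested baseline window contains too few breaths to characterize."""


class FormatError(ValueError):
    """An input file does not conform to the expected on-disk format."""


class DegenerateModelWarning(UserWarning):
    """The classifier was trained on a single outcome class."""


class RightCensoredWarning(UserWarning):
    """The recording ended before breathing normalized; metrics are censored."""
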