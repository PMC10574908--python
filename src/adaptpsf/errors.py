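"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: InputError -> 2, ParameterError -> 3,
NumericError -> 4, ConvergenceWarning is a flag, not an exception.
"""


class AdaptPSFError(Exception):
    """Base class for all package errors."""


class InputError(AdaptPSFError):
    """Invalid or inconsistent input data (shape mismatch, negative pixels, bad file)."""


class ParameterError(AdaptPSFError, ValueError):
    """Invalid configuration or parameter value."""


class NumericError(AdaptPSFError):
    """Degenerate or failed numeric computation (degenerate fit, undefined metric)."""


class DetectionError(AdaptPSFError):
    """A required image feature (e.g. a slit) could not be located."""
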