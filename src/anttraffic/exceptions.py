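"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors -> 2,
data-format errors -> 3, fit failures -> 4.
"""


class AntTrafficError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AntTrafficError, ValueError):
    """Invalid generator or pipeline configuration."""


class DataFormatError(AntTrafficError, ValueError):
    """Malformed or degenerate input data (bad CSV, missing columns, no spread)."""


class FitConvergenceError(AntTrafficError, RuntimeError):
    """A nonlinear fit failed to converge after restarts."""
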